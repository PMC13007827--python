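"""Interictal iEEG band power: preprocessing, Welch spectra, per-contact
relative band powers, contact-to-ROI assignment, and regional abnormality.

The analysis chain follows standard interictal band-power mapping: resample
to 200 Hz with anti-alias filtering, common average reference, a 70-s
interictal epoch, Welch PSD with 2-s Hamming windows and 1-s overlap
(0.5 Hz resolution), band powers over delta (1-4), theta (4-8), alpha
(8-13), beta (13-30), and gamma (30-80 Hz), normalized per contact so the
five relative powers sum to one.  log10 relative powers feed the normative
z-scoring; the regional abnormality score is the maximum |z| across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly, welch

from .synthetic import BANDS, BAND_EDGES

__all__ = ["Recording", "preprocess", "extract_epoch", "welch_psd",
           "band_powers", "assign_contacts", "regional_band_power",
           "ieeg_abnormality"]


@dataclass
class Recording:
    """Multichannel recording: (channels x samples) array at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids length does not match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def preprocess(rec: Recording, target_rate: float = 200.0,
               car: bool = True, notch_hz: float | None = None) -> Recording:
    """Anti-alias resample to ``target_rate`` and apply a common average
    reference.  Upsampling is refused.  An optional notch is provided for
    line-noise-contaminated data but is off by default."""
    if rec.fs < target_rate:
        raise ValueError(f"cannot upsample {rec.fs} Hz to {target_rate} Hz")
    data = rec.data
    if rec.fs != target_rate:
        frac = Fraction(target_rate / rec.fs).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    if notch_hz is not None:
        from scipy.signal import iirnotch, filtfilt
        b, a = iirnotch(notch_hz, Q=30.0, fs=target_rate)
        data = filtfilt(b, a, data, axis=-1)
    if car:
        data = data - data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=target_rate, channel_ids=rec.channel_ids)


def extract_epoch(rec: Recording, length_s: float = 70.0, offset_s: float = 0.0,
                  epoch_time_s: float | None = None,
                  last_seizure_time_s: float | None = None,
                  min_postseizure_s: float = 7200.0) -> Recording:
    """Contiguous interictal epoch.

    If seizure timing metadata is supplied, epochs closer than
    ``min_postseizure_s`` (default 2 h) to the preceding seizure are
    rejected; without metadata the criterion cannot be checked and the
    epoch is extracted as requested.
    """
    if offset_s < 0:
        raise ValueError("offset must be non-negative")
    if last_seizure_time_s is not None and epoch_time_s is not None:
        if epoch_time_s - last_seizure_time_s < min_postseizure_s:
            raise ValueError(
                f"epoch starts {epoch_time_s - last_seizure_time_s:.0f} s "
                f"postseizure, below the {min_postseizure_s:.0f} s minimum")
    i0 = int(round(offset_s * rec.fs))
    n = int(round(length_s * rec.fs))
    if i0 + n > rec.data.shape[1]:
        raise ValueError(
            f"recording too short: need {length_s + offset_s:.1f} s, "
            f"have {rec.duration_s:.1f} s")
    return replace(rec, data=rec.data[:, i0:i0 + n])


def welch_psd(rec: Recording, window_s: float = 2.0,
              overlap_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (density scaling, V^2/Hz).

    2-s Hamming windows with 1-s overlap at 200 Hz give 400-sample segments
    and 0.5-Hz resolution.  Returns (freqs, psd[channels x freqs]).
    """
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(overlap_s * rec.fs))
    if rec.data.shape[1] < nperseg:
        raise ValueError("epoch shorter than one Welch window")
    freqs, psd = welch(rec.data, fs=rec.fs, window="hamming", nperseg=nperseg,
                       noverlap=noverlap, detrend="constant", axis=-1,
                       scaling="density")
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                channel_ids: tuple[str, ...]) -> pd.DataFrame:
    """Per-contact band powers over the five canonical bands.

    Band power integrates the PSD over half-open bins [lo, hi) so shared
    edges are not double counted.  Relative powers are normalized to sum to
    1 per contact; log10 of the relative power is retained for z-scoring.

    Returns a long DataFrame: contact_id, band, power, rel_power,
    log10_rel_power.
    """
    psd = np.atleast_2d(psd)
    if freqs[-1] < BAND_EDGES["gamma"][1] - (freqs[1] - freqs[0]):
        raise ValueError("PSD does not cover the 1-80 Hz analysis range")
    df = float(freqs[1] - freqs[0])
    powers = np.column_stack([
        psd[:, (freqs >= lo) & (freqs < hi)].sum(axis=1) * df
        for lo, hi in (BAND_EDGES[b] for b in BANDS)])
    total = powers.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total band power in at least one contact")
    rel = powers / total[:, None]
    out = pd.DataFrame({
        "contact_id": np.repeat(channel_ids, len(BANDS)),
        "band": np.tile(BANDS, len(channel_ids)),
        "power": powers.ravel(),
        "rel_power": rel.ravel(),
    })
    out["log10_rel_power"] = np.log10(out["rel_power"])
    return out


def assign_contacts(contacts: pd.DataFrame, geometry: dict[str, np.ndarray],
                    gm_points: np.ndarray | None = None,
                    max_region_dist_mm: float = 5.0,
                    max_wm_gm_dist_mm: float = 2.0) -> pd.DataFrame:
    """Assign contacts to their nearest ROI by Euclidean distance.

    Exclusion rules: contacts farther than 5 mm from every ROI are dropped
    (``far_from_any_region``); white-matter contacts more than 2 mm from
    gray matter are dropped (``wm_far_from_gm``); contacts flagged in an
    optional boolean ``artifact`` column are dropped (``artifact``).

    ``geometry`` maps roi_id to an (n, 3) array of representative points in
    the same millimetre space as the contact coordinates.  ``gm_points``
    defaults to the union of all ROI points.
    """
    if not geometry:
        raise ValueError("empty parcellation geometry")
    roi_ids = sorted(geometry)
    coords = contacts[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if gm_points is None:
        gm_points = np.vstack([np.atleast_2d(geometry[r]) for r in roi_ids])
    rows = []
    for i, c in enumerate(contacts.itertuples()):
        dists = np.array([
            np.sqrt(((np.atleast_2d(geometry[r]) - coords[i]) ** 2).sum(axis=1)).min()
            for r in roi_ids])
        j = int(np.argmin(dists))
        nearest, dist = roi_ids[j], float(dists[j])
        gm_dist = float(np.sqrt(((gm_points - coords[i]) ** 2).sum(axis=1)).min())
        reason = "none"
        roi = nearest
        art = getattr(c, "artifact", False)
        if art is None or (isinstance(art, float) and np.isnan(art)):
            art = False
        if art:
            roi, reason = "EXCLUDED", "artifact"
        elif dist > max_region_dist_mm:
            roi, reason = "EXCLUDED", "far_from_any_region"
        elif getattr(c, "tissue", "GM") == "WM" and gm_dist > max_wm_gm_dist_mm:
            roi, reason = "EXCLUDED", "wm_far_from_gm"
        rows.append({"contact_id": c.contact_id, "roi_id": roi,
                     "distance_mm": dist, "exclusion_reason": reason})
    return pd.DataFrame(rows)


def regional_band_power(bp: pd.DataFrame, assignment: pd.DataFrame,
                        rois: list[str] | None = None) -> pd.DataFrame:
    """Average contact-level log10 relative band power within each ROI.

    ROIs without any assigned contact are reported with missing value and
    coverage='unsampled' (when a ROI universe is supplied).
    """
    kept = assignment[assignment["roi_id"] != "EXCLUDED"]
    merged = bp.merge(kept[["contact_id", "roi_id"]], on="contact_id")
    agg = (merged.groupby(["roi_id", "band"], sort=True)["log10_rel_power"]
           .mean().rename("value").reset_index())
    agg["coverage"] = "sampled"
    if rois is not None:
        missing = sorted(set(rois) - set(agg["roi_id"]))
        if missing:
            pad = pd.DataFrame([{"roi_id": r, "band": b, "value": np.nan,
                                 "coverage": "unsampled"}
                                for r in missing for b in BANDS])
            agg = pd.concat([agg, pad], ignore_index=True)
    return agg.sort_values(["roi_id", "band"]).reset_index(drop=True)


def ieeg_abnormality(zmap: pd.DataFrame) -> pd.DataFrame:
    """Regional iEEG abnormality: max |z| across the five bands.

    Input needs columns roi_id, band, z (per patient).  Rows with missing z
    are ignored; ROIs with no sampled band at all come back with missing
    score.  The achieving band and signed z are recorded.
    """
    def _reduce(g: pd.DataFrame) -> pd.Series:
        valid = g.dropna(subset=["z"])
        if valid.empty:
            return pd.Series({"score": np.nan, "band": None, "signed_z": np.nan,
                              "coverage": "unsampled"})
        i = valid["z"].abs().idxmax()
        return pd.Series({"score": abs(valid.loc[i, "z"]),
                          "band": valid.loc[i, "band"],
                          "signed_z": valid.loc[i, "z"],
                          "coverage": "sampled"})

    keys = [k for k in ("patient_id", "roi_id") if k in zmap.columns]
    out = zmap.groupby(keys, sort=True).apply(_reduce, include_groups=False)
    return out.reset_index()
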