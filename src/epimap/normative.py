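"""Normative maps: covariate-adjusted regional reference distributions.

A normative map stores, per ROI (and per frequency band for iEEG), a linear
age/sex model fitted on controls together with the residual SD.  Patients
are z-scored against the model's prediction for their own age and sex:

    z = (value - predicted_mean) / sd

Signs are preserved — volume loss gives negative z, increased diffusivity
positive z.  Regions without normative coverage propagate as missing with a
coverage flag, never as z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

__all__ = ["NormativeMap", "build_normative_map", "zscore_patients",
           "control_self_calibration"]

_KEYS = ["roi_id", "band"]


@dataclass
class NormativeMap:
    """Per-ROI (x band) normative model.

    ``table`` columns: roi_id, band, mean, sd, n_controls, coef_intercept,
    coef_age, coef_sexM.  ``sd`` is clamped from below at ``sd_floor``.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = ("age", "sex")
    sd_floor: float = 1e-6
    warnings: list = field(default_factory=list)

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        merged = rows.merge(self.table, on=_keys_present(rows, self.table),
                            how="left")
        pred = (merged["coef_intercept"]
                + merged["coef_age"] * merged["age"]
                + merged["coef_sexM"] * (merged["sex"] == "M"))
        pred.index = rows.index
        return pred

    def to_json(self, path) -> None:
        payload = {"covariates": list(self.covariates), "sd_floor": self.sd_floor,
                   "table": self.table.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeMap":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(table=pd.DataFrame(payload["table"]),
                   covariates=tuple(payload["covariates"]),
                   sd_floor=payload["sd_floor"])


def _keys_present(df: pd.DataFrame, table: pd.DataFrame) -> list[str]:
    return [k for k in _KEYS if k in df.columns and k in table.columns]


def _fit_group(g: pd.DataFrame) -> tuple[float, float, float, float, float]:
    y = g["value"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(g)), g["age"].to_numpy(dtype=float),
                         (g["sex"] == "M").to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(g) - np.linalg.matrix_rank(X), 1)
    sd = float(np.sqrt((resid ** 2).sum() / dof))
    return float(beta[0]), float(beta[1]), float(beta[2]), sd, float(y.mean())


def build_normative_map(controls: pd.DataFrame, sd_floor: float = 1e-6,
                        n_min: int = 10) -> NormativeMap:
    """Fit the per-ROI covariate model on a (harmonized) control table.

    Groups with fewer than ``n_min`` controls are dropped with a warning
    entry; residual SDs below ``sd_floor`` are clamped (degenerate, e.g.
    constant synthetic data).
    """
    keys = [k for k in _KEYS if k in controls.columns and controls[k].notna().any()]
    if not keys:
        raise ValueError("controls table has no roi_id column")
    rows, warnings = [], []
    for key_vals, g in controls.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rec = dict(zip(keys, key_vals))
        if len(g) < n_min:
            warnings.append(f"{rec}: only {len(g)} controls (< {n_min}), skipped")
            continue
        b0, b_age, b_sex, sd, mean = _fit_group(g)
        if sd < sd_floor:
            warnings.append(f"{rec}: residual sd {sd:.3g} clamped to floor")
            sd = sd_floor
        rec.update({"mean": mean, "sd": sd, "n_controls": len(g),
                    "coef_intercept": b0, "coef_age": b_age, "coef_sexM": b_sex})
        rows.append(rec)
    if not rows:
        raise ValueError("no ROI had enough controls to fit a normative model")
    table = pd.DataFrame(rows)
    if "band" not in table.columns:
        table["band"] = None
    return NormativeMap(table=table, sd_floor=sd_floor, warnings=warnings)


def zscore_patients(patients: pd.DataFrame, nmap: NormativeMap) -> pd.DataFrame:
    """Z-score a patient feature table against a normative map.

    Returns columns patient_id, roi_id[, band], modality, z, coverage.
    ROIs (or bands) absent from the map are kept with coverage='unsampled'
    and missing z.
    """
    keys = _keys_present(patients, nmap.table)
    merged = patients.merge(nmap.table, on=keys, how="left")
    pred = (merged["coef_intercept"] + merged["coef_age"] * merged["age"]
            + merged["coef_sexM"] * (merged["sex"] == "M"))
    z = (merged["value"] - pred) / merged["sd"]
    out = pd.DataFrame({
        "patient_id": merged["subject_id"],
        "roi_id": merged["roi_id"],
        "band": merged["band_x"] if "band_x" in merged else merged.get("band"),
        "modality": merged.get("modality"),
        "z": z,
        "coverage": np.where(merged["sd"].notna(), "sampled", "unsampled"),
    })
    out.loc[out["coverage"] == "unsampled", "z"] = np.nan
    return out


def control_self_calibration(controls: pd.DataFrame, sd_floor: float = 1e-6,
                             n_min: int = 10) -> dict:
    """Leave-one-out z-score calibration of the normative model.

    Each control is z-scored against a map built without it.  Returns the
    pooled z mean/SD and a per-ROI summary — for well-specified Gaussian
    controls the pooled z should have mean ~0 and SD ~1; heavy tails are
    reported as SD > 1, not hidden.
    """
    subjects = controls["subject_id"].unique()
    if len(subjects) < n_min:
        raise ValueError(f"need at least {n_min} controls for calibration")
    zs = []
    for sid in subjects:
        held = controls[controls["subject_id"] == sid]
        rest = controls[controls["subject_id"] != sid]
        nmap = build_normative_map(rest, sd_floor=sd_floor, n_min=n_min - 1)
        zs.append(zscore_patients(held, nmap))
    allz = pd.concat(zs, ignore_index=True)
    sampled = allz[allz["coverage"] == "sampled"]
    keys = [k for k in _KEYS if k in sampled.columns and sampled[k].notna().any()]
    per_roi = (sampled.groupby(keys)["z"].agg(["mean", "std", "count"])
               .reset_index())
    return {"pooled_mean": float(sampled["z"].mean()),
            "pooled_sd": float(sampled["z"].std(ddof=1)),
            "n": int(len(sampled)),
            "per_roi": per_roi,
            "zscores": allz}
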