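"""Patient-specific abnormal-region sets from ranked z-scores.

Per modality, regional abnormality scores are ranked with the expected
abnormal direction first: gray-matter volume z ascending (most negative
first), superficial-white-matter MD z descending (most positive first),
iEEG max-|z| descending.  A Bayesian mean-shift change point on the ranked
curve separates the abnormal head segment from the rest of the
distribution, and modalities are combined by set union.

The ranked curve of a patient with *no* abnormality is not flat: it traces
the quantile curve of the null score distribution, which a
piecewise-constant mean-shift model will happily cut near the middle.  The
detector therefore works on the residual between the ranked curve and the
expected null order statistics (standard normal for signed z; the maximum
absolute value of five standard normals for the iEEG max-|z| score):

1. *Detection gate* — a scan statistic ``max_k sqrt(k) * mean(r[1..k])``
   over the oriented residual ``r``, calibrated against a deterministic
   Monte-Carlo null at level ``scan_alpha``.  Patients indistinguishable
   from the null get an empty abnormal set.
2. *Segmentation* — recursive single-change-point cuts on the residual;
   the first segment must clear ``min_effect`` (robust-SD units above the
   null curve), later extensions the smaller ``segment_gate``.  If the
   segmentation finds nothing but the gate fired, the scan maximizer is
   used as the cut.

Signed-z residuals are robust-standardized (median/MAD), which makes the
MRI sets invariant to affine transforms of the scores.  iEEG max-|z|
scores are compared to the null curve in their own calibrated units
because implantation deliberately targets suspected tissue, so the sampled
regions can be majority-abnormal and a within-patient scale estimate would
be contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

from .changepoint import ChangePointConfig, detect_change_point
from .synthetic import BANDS, GM, IEEG, SWM

__all__ = ["RankedSequence", "AbnormalSet", "AbnormalityConfig", "rank_regions",
           "abnormal_set", "union_abnormalities", "cohort_prevalence",
           "MODALITY_DIRECTIONS"]

# which end of the score distribution is abnormal
MODALITY_DIRECTIONS = {GM: "most_negative_first",
                       SWM: "most_positive_first",
                       IEEG: "most_positive_first"}


@dataclass(frozen=True)
class RankedSequence:
    roi_ids: tuple[str, ...]
    scores: np.ndarray
    direction: str
    modality: str


@dataclass(frozen=True)
class AbnormalSet:
    patient_id: str
    modality: str                       # modality name or union tag
    rois: frozenset[str]
    k: int                              # change-point index (head length)
    log_bf: float                       # change vs no-change evidence at the cut
    provenance: dict = field(default_factory=dict)   # roi -> contributing modalities


@dataclass(frozen=True)
class AbnormalityConfig:
    """Thresholding parameters.

    ``scan_alpha`` is the null level of the detection gate for the signed-z
    (MRI) modalities; ``scan_alpha_ieeg`` for the iEEG max-|z| score, whose
    absolute-unit test is more powerful and whose sampled universe is
    small.  ``min_effect`` / ``segment_gate`` are in robust-SD units above
    the expected null curve.
    """

    scan_alpha: float = 0.2
    scan_alpha_ieeg: float = 0.1
    min_effect: float = 0.3
    segment_gate: float = 0.1
    n_null_sims: int = 4000
    changepoint: ChangePointConfig = ChangePointConfig()


def rank_regions(zmap: pd.DataFrame, modality: str,
                 score_col: str | None = None) -> RankedSequence:
    """Rank non-missing regional scores in the modality's abnormal-first
    order; ties broken deterministically by roi_id."""
    if modality not in MODALITY_DIRECTIONS:
        raise ValueError(f"unknown modality {modality!r}")
    col = score_col or ("score" if modality == IEEG else "z")
    valid = zmap.dropna(subset=[col])
    if len(valid) < 3:
        raise ValueError(f"need >= 3 non-missing regions, got {len(valid)}")
    direction = MODALITY_DIRECTIONS[modality]
    ascending = direction == "most_negative_first"
    ordered = valid.sort_values([col, "roi_id"],
                                ascending=[ascending, True], kind="mergesort")
    return RankedSequence(roi_ids=tuple(ordered["roi_id"]),
                          scores=ordered[col].to_numpy(dtype=float),
                          direction=direction, modality=modality)


def _kind(modality: str) -> str:
    return "ieeg" if modality == IEEG else "signed_z"


def _null_quantiles(n: int, modality: str) -> np.ndarray:
    """Expected null order statistics in the modality's ranking order
    (Blom plotting positions)."""
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    if _kind(modality) == "ieeg":
        # max of five absolute standard normals: F(m) = (2*Phi(m) - 1)^5
        q = norm.ppf((1.0 + p ** (1.0 / len(BANDS))) / 2.0)
        return q[::-1].copy()                       # descending, abnormal first
    q = norm.ppf(p)
    if MODALITY_DIRECTIONS[modality] == "most_negative_first":
        return q
    return q[::-1].copy()


def _robust_standardize(x: np.ndarray) -> np.ndarray | None:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    return (x - med) / (1.4826 * mad)


def oriented_residual(seq: RankedSequence) -> np.ndarray | None:
    """Ranked-curve residual against the expected null curve, oriented so
    abnormality is positive at the head.  None for constant sequences."""
    b = _null_quantiles(len(seq.scores), seq.modality)
    if _kind(seq.modality) == "ieeg":
        return seq.scores - b
    s = _robust_standardize(seq.scores)
    bs = _robust_standardize(b)
    if s is None or bs is None:
        return None
    sign = -1.0 if seq.direction == "most_negative_first" else 1.0
    return sign * (s - bs)


def _scan_curve(r: np.ndarray) -> np.ndarray:
    ks = np.arange(1, max(len(r) // 2, 1) + 1)
    return np.sqrt(ks) * (np.cumsum(r)[:len(ks)] / ks)


@lru_cache(maxsize=64)
def _scan_threshold(n: int, kind: str, alpha: float, n_sim: int) -> float:
    """(1 - alpha) quantile of the scan statistic under the null score
    model, from a deterministic Monte-Carlo simulation."""
    rng = np.random.default_rng(
        np.random.SeedSequence([772_003, n, 1 if kind == "ieeg" else 0]))
    stats = np.empty(n_sim)
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    if kind == "ieeg":
        b = norm.ppf((1.0 + p ** (1.0 / len(BANDS))) / 2.0)[::-1]
        for i in range(n_sim):
            s = np.sort(np.abs(rng.standard_normal((n, len(BANDS)))).max(axis=1))[::-1]
            stats[i] = _scan_curve(s - b).max()
    else:
        bs = _robust_standardize(norm.ppf(p))
        for i in range(n_sim):
            s = _robust_standardize(np.sort(rng.standard_normal(n)))
            stats[i] = _scan_curve(-(s - bs)).max()
    return float(np.quantile(stats, 1.0 - alpha))


def abnormal_set(zmap: pd.DataFrame, modality: str, patient_id: str | None = None,
                 config: AbnormalityConfig | None = None,
                 score_col: str | None = None) -> AbnormalSet:
    """Rank one patient's regional scores, detect the change-point
    threshold, and return the abnormal head segment as a set."""
    cfg = config or AbnormalityConfig()
    seq = rank_regions(zmap, modality, score_col=score_col)
    if patient_id is not None:
        pid = patient_id
    elif "patient_id" in zmap.columns:
        pid = str(zmap["patient_id"].iloc[0])
    else:
        pid = ""
    empty = AbnormalSet(patient_id=pid, modality=modality, rois=frozenset(),
                        k=0, log_bf=float("-inf"))
    r = oriented_residual(seq)
    if r is None:
        return empty

    alpha = cfg.scan_alpha_ieeg if _kind(modality) == "ieeg" else cfg.scan_alpha
    scan = _scan_curve(r)
    if scan.max() < _scan_threshold(len(r), _kind(modality), alpha, cfg.n_null_sims):
        return empty

    # recursive mean-shift segmentation of the residual
    start, k_total, log_bf = 0, 0, float("-inf")
    while True:
        tail = r[start:]
        if len(tail) < 3:
            break
        res = detect_change_point(tail, cfg.changepoint)
        if res.k == 0:
            break
        head, rest = tail[:res.k], tail[res.k:]
        gate = cfg.min_effect if start == 0 else cfg.segment_gate
        if head.mean() < gate or head.mean() <= rest.mean():
            break
        if start == 0:
            log_bf = res.log_bf
        k_total = start + res.k
        start = k_total
    if k_total == 0:
        # detection fired but no segment cleared the gates: cut at the
        # scan maximizer provided the head clears the first-segment gate
        k_scan = int(np.argmax(scan)) + 1
        if r[:k_scan].mean() >= cfg.min_effect:
            k_total, log_bf = k_scan, scan.max()
    if k_total == 0:
        return empty
    return AbnormalSet(patient_id=pid, modality=modality,
                       rois=frozenset(seq.roi_ids[:k_total]),
                       k=k_total, log_bf=log_bf,
                       provenance={roi: (modality,) for roi in seq.roi_ids[:k_total]})


def union_abnormalities(sets: list[AbnormalSet], tag: str = "union") -> AbnormalSet:
    """Union of per-modality abnormal sets for one patient, with per-ROI
    provenance.  iEEG contributes only over its sampled coverage — the
    per-modality sets already contain sampled regions only."""
    if not sets:
        raise ValueError("no abnormal sets to combine")
    pids = {s.patient_id for s in sets}
    if len(pids) > 1:
        raise ValueError(f"sets from different patients: {sorted(pids)}")
    provenance: dict[str, tuple] = {}
    for s in sets:
        for roi in s.rois:
            for m in s.provenance.get(roi, (s.modality,)):
                provenance[roi] = tuple(sorted(set(provenance.get(roi, ())) | {m}))
    rois = frozenset(provenance)
    return AbnormalSet(patient_id=pids.pop(), modality=tag, rois=rois,
                       k=len(rois), log_bf=max(s.log_bf for s in sets),
                       provenance=provenance)


def cohort_prevalence(sets: list[AbnormalSet], rois: list[str]) -> pd.DataFrame:
    """Fraction of patients in which each ROI is abnormal (spatial
    distribution reporting)."""
    n = len({s.patient_id for s in sets})
    counts = {r: 0 for r in rois}
    for s in sets:
        for r in s.rois:
            if r in counts:
                counts[r] += 1
    return pd.DataFrame({"roi_id": list(counts),
                         "fraction_abnormal": [counts[r] / n for r in counts]})
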