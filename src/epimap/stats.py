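"""Resection-overlap scoring and outcome-differentiation statistics.

The central quantity is, per patient, the proportion of abnormal regions
that were resected (a region counts as resected when more than 10% of its
volume overlaps the resection mask).  Outcome groups — free of disabling
seizures (ILAE class 1-2) versus not (ILAE 3+) — are compared with:

* AUC in the Mann-Whitney formulation and the step-rule AUPRC,
* a one-tailed Wilcoxon rank-sum test (seizure-free patients hypothesized
  to have higher proportions resected),
* the DeLong test for paired (correlated) ROC curves when adding iEEG to
  the MRI abnormality map,
* binomial logistic regressions for colocalization (is an MRI-abnormal
  region more likely to be implanted / iEEG-abnormal?), per outcome group,
* Yates-corrected chi-square and Kruskal-Wallis for cohort tables, and a
  leave-one-out threshold cross-validation of outcome classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score

from .abnormality import AbnormalSet

__all__ = ["SurgeryRecord", "OverlapScore", "resected_set",
           "proportion_abnormal_resected", "auc", "auprc",
           "ranksum_one_tailed", "delong_paired", "colocalization_logistic",
           "chi_square_yates", "kruskal_wallis", "loo_outcome_cv", "lateralize",
           "SeparationError", "RESECTED_OVERLAP_THRESHOLD"]

RESECTED_OVERLAP_THRESHOLD = 0.10     # strictly greater-than


class SeparationError(RuntimeError):
    """Raised when a logistic model is perfectly separated."""


@dataclass(frozen=True)
class SurgeryRecord:
    patient_id: str
    resected_rois: frozenset[str]
    implanted_rois: frozenset[str]
    outcome: str                       # ILAE12 | ILAE3plus
    side: str                          # left | right


@dataclass(frozen=True)
class OverlapScore:
    patient_id: str
    modality: str
    proportion_resected: float | None  # None iff abnormal set empty
    n_abnormal: int
    n_resected_abnormal: int


def resected_set(overlaps: pd.DataFrame,
                 threshold: float = RESECTED_OVERLAP_THRESHOLD) -> frozenset[str]:
    """Regions counted as resected: overlap fraction strictly greater than
    the 10% threshold."""
    hit = overlaps.loc[overlaps["overlap_fraction"] > threshold, "roi_id"]
    return frozenset(hit)


def proportion_abnormal_resected(abnormal: AbnormalSet,
                                 surgery: SurgeryRecord) -> OverlapScore:
    """|abnormal ∩ resected| / |abnormal|; missing (flagged) when the
    abnormal set is empty."""
    n_abn = len(abnormal.rois)
    n_hit = len(abnormal.rois & surgery.resected_rois)
    prop = None if n_abn == 0 else n_hit / n_abn
    return OverlapScore(patient_id=surgery.patient_id, modality=abnormal.modality,
                        proportion_resected=prop, n_abnormal=n_abn,
                        n_resected_abnormal=n_hit)


def _clean_groups(pos, neg):
    pos = np.asarray([p for p in pos if p is not None and not np.isnan(p)], dtype=float)
    neg = np.asarray([p for p in neg if p is not None and not np.isnan(p)], dtype=float)
    return pos, neg


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(tie).  Missing scores are
    excluded before calling (callers report the count)."""
    pos, neg = _clean_groups(pos_scores, neg_scores)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by the step-wise
    (non-interpolated) rule; positives are the seizure-free group."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("no positive labels")
    return float(average_precision_score(labels, scores))


def _midranks_pvalue_normal(x, y) -> tuple[float, float]:
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(w), 1.0
    z = (w - mu - 0.5) / np.sqrt(var)     # continuity-corrected, upper tail
    return float(w), float(sps.norm.sf(z))


def ranksum_one_tailed(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum test of x stochastically greater than y.

    Midranks for ties; the p-value is exact by enumeration of all
    assignments when n_x + n_y <= ``exact_max_n``, otherwise a
    tie-corrected, continuity-corrected normal approximation.
    Returns (rank-sum of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        ranks = sps.rankdata(pooled)
        return float(ranks[:len(x)].sum()), 1.0
    if len(pooled) <= exact_max_n:
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:len(x)].sum()
        count = total = 0
        for idx in combinations(range(len(pooled)), len(x)):
            w = ranks[list(idx)].sum()
            total += 1
            if w >= w_obs - 1e-12:
                count += 1
        return float(w_obs), count / total
    return _midranks_pvalue_normal(x, y)


def _placements(pos, neg):
    """DeLong structural components (placement values)."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_paired(scores_a, scores_b, labels) -> dict:
    """DeLong test comparing two correlated AUCs on the same subjects.

    Subjects with a missing score in either set are dropped pairwise (the
    count is reported).  Returns dict with auc_a, auc_b, z, p (two-sided),
    n_dropped.  The z sign convention is auc_a - auc_b.
    """
    sa = np.asarray([np.nan if s is None else s for s in scores_a], dtype=float)
    sb = np.asarray([np.nan if s is None else s for s in scores_b], dtype=float)
    lab = np.asarray(labels, dtype=int)
    keep = ~(np.isnan(sa) | np.isnan(sb))
    n_dropped = int((~keep).sum())
    sa, sb, lab = sa[keep], sb[keep], lab[keep]
    if lab.sum() == 0 or lab.sum() == len(lab):
        raise ValueError("both outcome groups must be present after dropping")
    pos, neg = lab == 1, lab == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 subjects per group")
    aucs, v10s, v01s = [], [], []
    for s in (sa, sb):
        v10, v01 = _placements(s[pos], s[neg])
        aucs.append(v10.mean())
        v10s.append(v10)
        v01s.append(v01)
    s10 = np.cov(np.vstack(v10s))      # 2x2 across score sets
    s01 = np.cov(np.vstack(v01s))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    d = aucs[0] - aucs[1]
    if var <= 0:
        if d == 0:
            return {"auc_a": aucs[0], "auc_b": aucs[1], "z": 0.0, "p": 1.0,
                    "n_dropped": n_dropped}
        raise ValueError("zero variance estimate for a nonzero AUC difference; "
                         "scores may be degenerate")
    z = d / np.sqrt(var)
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]), "z": float(z),
            "p": float(2 * sps.norm.sf(abs(z))), "n_dropped": n_dropped}


def colocalization_logistic(predictor, response) -> dict:
    """Binomial logistic regression of a binary response (implanted, or
    iEEG-abnormal) on a binary predictor (MRI-abnormal), pooling
    (patient, ROI) observations.

    Complete separation is detected and raised as SeparationError rather
    than silently returning a huge coefficient.  Returns dict with coef,
    z (Wald), p (one observation per row).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0} or set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("predictor and response must be binary")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("predictor and response must both vary")
    # 2x2 margins: separation iff a predictor level is pure in the response
    p1 = y[x == 1].mean()
    p0 = y[x == 0].mean()
    if p1 in (0.0, 1.0) or p0 in (0.0, 1.0):
        raise SeparationError("complete or quasi-complete separation")
    import statsmodels.api as sm
    model = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
    res = model.fit()
    coef = float(res.params[1])
    se = float(res.bse[1])
    z = coef / se
    return {"coef": coef, "se": se, "z": float(z),
            "p": float(2 * sps.norm.sf(abs(z))), "n": len(y)}


def chi_square_yates(table) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=True)
    assert dof == 1
    return float(chi2), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.all(a == arrays[0][0]) for a in arrays if len(a)):
        return 0.0, 1.0
    k, p = sps.kruskal(*arrays)
    return float(k), float(p)


def loo_outcome_cv(scores, labels) -> dict:
    """Leave-one-out cross-validated outcome classification.

    For each held-out patient a threshold on the proportion-resected score
    is chosen to maximize balanced accuracy on the remaining patients
    (ties resolved toward the lowest threshold); the held-out prediction
    is score > threshold.  Returns per-patient predictions, held-out
    accuracy and held-out AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("need >= 3 patients per class")
    preds = np.empty(len(y), dtype=int)
    thresholds_used = np.empty(len(y))
    for i in range(len(y)):
        tr = np.ones(len(y), dtype=bool)
        tr[i] = False
        st, yt = s[tr], y[tr]
        uniq = np.unique(st)
        cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0]) \
            if len(uniq) > 1 else np.array([uniq[0] - 1.0])
        best_t, best_ba = cand[0], -1.0
        for t in cand:
            pred = st > t
            sens = pred[yt == 1].mean()
            spec = (~pred[yt == 0]).mean()
            ba = (sens + spec) / 2.0
            if ba > best_ba + 1e-12:
                best_t, best_ba = t, ba
        thresholds_used[i] = best_t
        preds[i] = int(s[i] > best_t)
    acc = float((preds == y).mean())
    heldout_auc = auc(s[y == 1], s[y == 0])
    return {"predictions": preds, "thresholds": thresholds_used,
            "accuracy": acc, "auc": heldout_auc}


def lateralize(roi_table: pd.DataFrame, side: str) -> pd.DataFrame:
    """Relabel ROIs relative to the surgery side: same hemisphere ->
    ipsilateral, other -> contralateral.  Deep structures keep their flag
    so reports can separate them."""
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    out = roi_table.copy()
    out["laterality"] = np.where(out["hemisphere"] == side, "ipsilateral",
                                 "contralateral")
    return out
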