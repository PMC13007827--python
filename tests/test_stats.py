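"""Outcome statistics against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from epimap.abnormality import AbnormalSet
from epimap.stats import (SeparationError, SurgeryRecord, auc, auprc,
                          chi_square_yates, colocalization_logistic,
                          delong_paired, kruskal_wallis, lateralize,
                          loo_outcome_cv, proportion_abnormal_resected,
                          ranksum_one_tailed, resected_set)


def _aset(rois):
    return AbnormalSet(patient_id="p", modality="MRI", rois=frozenset(rois),
                       k=len(rois), log_bf=0.0)


def _surgery(resected):
    return SurgeryRecord(patient_id="p", resected_rois=frozenset(resected),
                         implanted_rois=frozenset(), outcome="ILAE12",
                         side="left")


def test_proportion_resected_examples():
    assert proportion_abnormal_resected(
        _aset({"A", "B", "C", "D"}), _surgery({"A", "B"})).proportion_resected == 0.5
    assert proportion_abnormal_resected(
        _aset({"A", "B"}), _surgery({"A", "B", "C"})).proportion_resected == 1.0
    empty = proportion_abnormal_resected(_aset(set()), _surgery({"A"}))
    assert empty.proportion_resected is None and empty.n_abnormal == 0


def test_resected_flag_strictly_above_ten_percent():
    df = pd.DataFrame({"roi_id": ["a", "b"], "overlap_fraction": [0.10, 0.101]})
    assert resected_set(df) == {"b"}


def test_auc_trivial_cases():
    assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0
    assert auc([1, 2, 3], [1, 2, 3]) == 0.5
    with pytest.raises(ValueError):
        auc([], [1.0])


def test_auc_matches_pair_counting_oracle():
    for trial in range(100):
        rng = np.random.default_rng(trial)
        pos = rng.normal(0.5, 1, rng.integers(2, 15))
        neg = rng.normal(0.0, 1, rng.integers(2, 15))
        if trial % 3 == 0:                     # inject ties
            pos = np.round(pos)
            neg = np.round(neg)
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert auc(pos, neg) == pytest.approx(brute, abs=1e-12)


def test_auprc_known_values():
    assert auprc([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0]) == 1.0
    # single positive ranked last of four: AP = precision there = 1/4
    assert auprc([0.1, 0.5, 0.6, 0.7], [1, 0, 0, 0]) == pytest.approx(0.25)


def test_auprc_null_equals_prevalence():
    # random ranking: mean AP approaches the prevalence (small positive
    # finite-sample bias, so a comfortably sized sample is used)
    rng = np.random.default_rng(0)
    vals = []
    labels = np.array([1] * 50 + [0] * 150)
    for _ in range(300):
        vals.append(auprc(rng.random(200), labels))
    assert np.mean(vals) == pytest.approx(0.25, abs=0.05)


def test_ranksum_exact_small_sample():
    w, p = ranksum_one_tailed([4, 5, 6], [1, 2, 3])
    assert p == pytest.approx(1 / 20)
    _, p_tied = ranksum_one_tailed([1, 2, 3], [1, 2, 3])
    assert p_tied >= 0.5


def test_ranksum_all_tied_reports_one():
    _, p = ranksum_one_tailed([2, 2], [2, 2, 2])
    assert p == 1.0


def test_ranksum_normal_approximation_close_to_exact():
    for trial in range(30):
        rng = np.random.default_rng(50 + trial)
        x = rng.normal(0.3, 1, 6)
        y = rng.normal(0.0, 1, 6)
        _, p_exact = ranksum_one_tailed(x, y)
        _, p_norm = ranksum_one_tailed(x, y, exact_max_n=0)
        assert abs(p_exact - p_norm) < 0.01


def test_ranksum_type_one_error_calibrated():
    """One-tailed rank-sum at alpha = 0.05, n = 19 vs 21: type-I error over
    2000 null replicates stays within [0.03, 0.07]."""
    rng = np.random.default_rng(77)
    rejections = 0
    for _ in range(2000):
        x = rng.standard_normal(19)
        y = rng.standard_normal(21)
        rejections += ranksum_one_tailed(x, y)[1] < 0.05
    assert 0.03 <= rejections / 2000 <= 0.07


def test_delong_identical_scores():
    labels = [1, 1, 0, 0, 1]
    s = [0.9, 0.7, 0.3, 0.2, 0.8]
    out = delong_paired(s, s, labels)
    assert out["z"] == 0.0 and out["p"] == 1.0


def test_delong_antisymmetric():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 2, 40)
    labels[:3] = 1
    labels[-3:] = 0
    a = rng.random(40) + 0.3 * labels
    b = rng.random(40) + 0.1 * labels
    ab = delong_paired(a, b, labels)
    ba = delong_paired(b, a, labels)
    assert ab["z"] == pytest.approx(-ba["z"])


def test_delong_variance_against_paired_bootstrap():
    """The placement-value variance of AUC_A - AUC_B is within [0.7, 1.3]
    of a 2000-replicate paired bootstrap at n = 40."""
    rng = np.random.default_rng(11)
    labels = np.array([1] * 19 + [0] * 21)
    a = rng.random(40) + 0.5 * labels
    b = 0.6 * a + 0.4 * rng.random(40)
    out = delong_paired(a, b, labels)
    se_delong = abs(out["auc_a"] - out["auc_b"]) / abs(out["z"])
    diffs = []
    idx_pos, idx_neg = np.where(labels == 1)[0], np.where(labels == 0)[0]
    for _ in range(2000):
        bp = rng.choice(idx_pos, len(idx_pos))
        bn = rng.choice(idx_neg, len(idx_neg))
        keep = np.concatenate([bp, bn])
        lab = labels[keep]
        diffs.append(auc(a[keep][lab == 1], a[keep][lab == 0])
                     - auc(b[keep][lab == 1], b[keep][lab == 0]))
    ratio = se_delong / np.std(diffs)
    assert 0.7 <= ratio <= 1.3


def test_delong_missing_scores_dropped_pairwise():
    labels = [1, 1, 1, 0, 0, 0]
    out = delong_paired([0.9, None, 0.7, 0.1, 0.2, 0.3],
                        [0.8, 0.6, 0.5, 0.2, 0.1, 0.4], labels)
    assert out["n_dropped"] == 1


def test_delong_power_exceeds_null_rate():
    """A planted AUC difference is rejected more often than under the
    null at alpha = 0.05."""
    rng = np.random.default_rng(21)
    labels = np.array([1] * 20 + [0] * 20)

    def rejection_rate(delta):
        hits = 0
        for _ in range(300):
            signal = rng.random(40) + 0.8 * delta * labels
            a = signal + 0.2 * rng.random(40)
            b = rng.permutation(signal) + 0.2 * rng.random(40)
            try:
                hits += delong_paired(a, b, labels)["p"] < 0.05
            except ValueError:
                pass
        return hits / 300

    assert rejection_rate(0.5) > rejection_rate(0.0) + 0.1


def test_logistic_matches_two_by_two_log_odds_ratio():
    rng = np.random.default_rng(9)
    x = rng.integers(0, 2, 300)
    p = np.where(x == 1, 0.7, 0.35)
    y = (rng.random(300) < p).astype(int)
    out = colocalization_logistic(x, y)
    n11 = ((x == 1) & (y == 1)).sum()
    n10 = ((x == 1) & (y == 0)).sum()
    n01 = ((x == 0) & (y == 1)).sum()
    n00 = ((x == 0) & (y == 0)).sum()
    log_or = np.log(n11 * n00 / (n10 * n01))
    assert out["coef"] == pytest.approx(log_or, abs=1e-6)


def test_logistic_null_calibration():
    rng = np.random.default_rng(31)
    inside = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.integers(0, 2, 200)
        y = rng.integers(0, 2, 200)
        try:
            inside += abs(colocalization_logistic(x, y)["z"]) <= 1.96
        except (SeparationError, ValueError):
            pass
    assert inside / n_rep == pytest.approx(0.95, abs=0.05)


def test_logistic_separation_raised():
    x = np.array([0, 0, 1, 1, 0, 1])
    with pytest.raises(SeparationError):
        colocalization_logistic(x, x)


def test_chi_square_matches_printed_cohort_tables():
    chi2_side, _ = chi_square_yates([[13, 6], [6, 15]])
    assert round(chi2_side, 2) == 4.85
    chi2_hs, _ = chi_square_yates([[9, 10], [12, 9]])
    assert round(chi2_hs, 2) == 0.09
    chi2_null, p = chi_square_yates([[10, 10], [10, 10]])
    assert chi2_null == 0.0 and p == 1.0


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_square_yates([[0, 0], [5, 5]])


def test_kruskal_identical_groups_zero():
    k, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0, 1.0])
    assert k == 0.0


def test_kruskal_two_groups_equals_squared_ranksum_z():
    """For two tie-free groups, the Kruskal-Wallis statistic equals the
    square of the standardized rank-sum statistic."""
    rng = np.random.default_rng(13)
    x = rng.normal(0.5, 1, 9)
    y = rng.normal(0.0, 1, 7)
    k, _ = kruskal_wallis(x, y)
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([x, y]))
    w = ranks[:9].sum()
    n1, n2 = 9, 7
    zsq = (w - n1 * (n1 + n2 + 1) / 2) ** 2 / (n1 * n2 * (n1 + n2 + 1) / 12)
    assert k == pytest.approx(zsq, rel=1e-9)


def test_kruskal_matches_manual_formula_small_n():
    rng = np.random.default_rng(17)
    groups = [rng.normal(size=3), rng.normal(size=3), rng.normal(size=2)]
    k, _ = kruskal_wallis(*groups)
    from scipy.stats import rankdata
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        h += r.sum() ** 2 / len(g)
        idx += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    assert k == pytest.approx(h, rel=1e-9)


def test_loo_cv_perfect_separation():
    out = loo_outcome_cv([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], [1, 1, 1, 0, 0, 0])
    assert out["accuracy"] == 1.0 and out["auc"] == 1.0


def test_loo_cv_hand_worked_example():
    """n=6 with one inverted pair: thresholds chosen on each fold by
    balanced accuracy classify exactly the consistent patients correctly."""
    scores = [0.9, 0.4, 0.7, 0.6, 0.2, 0.1]
    labels = [1, 1, 1, 0, 0, 0]
    out = loo_outcome_cv(scores, labels)
    # hand enumeration: folds place the threshold at 0.5 except when the
    # held-out subject is one of the two inconsistent ones (0.4 and 0.6)
    assert (out["predictions"] == np.array([1, 0, 1, 1, 0, 0])).all()
    assert out["accuracy"] == pytest.approx(4 / 6)


def test_loo_cv_null_accuracy_near_chance():
    rng = np.random.default_rng(19)
    accs = []
    for _ in range(200):
        scores = rng.random(20)
        labels = rng.permutation([1] * 10 + [0] * 10)
        accs.append(loo_outcome_cv(scores, labels)["accuracy"])
    assert np.mean(accs) == pytest.approx(0.5, abs=0.05)


def test_lateralize_relabels_by_surgery_side():
    parc = pd.DataFrame({"roi_id": ["L_hip", "R_hip", "R_amy"],
                         "name": ["hip", "hip", "amy"],
                         "hemisphere": ["left", "right", "right"],
                         "deep_flag": [True, True, True]})
    right = lateralize(parc, "right").set_index("roi_id")
    assert right.loc["R_hip", "laterality"] == "ipsilateral"
    assert right.loc["L_hip", "laterality"] == "contralateral"
    left = lateralize(parc, "left").set_index("roi_id")
    assert left.loc["R_amy", "laterality"] == "contralateral"
    with pytest.raises(ValueError):
        lateralize(parc, "bilateral")
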