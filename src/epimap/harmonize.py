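"""Batch-effect harmonization of regional feature tables.

Parametric empirical-Bayes location/scale adjustment (the ComBat model):
for feature (ROI) g and subject j in batch i,

    y_ijg = alpha_g + X_j' beta_g + gamma_ig + delta_ig * eps_ijg

Batch locations gamma and scales delta are estimated per ROI, shrunk across
ROIs (normal prior on gamma, inverse-gamma prior on delta^2, moment-matched
hyperparameters, iterative conditional posterior means), and removed while
covariate effects are preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["harmonize_batches", "combat"]

_FEATURE_KEYS = ["roi_id", "band"]


def _design(demo: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = []
    for cov in covariates:
        if demo[cov].isna().any():
            raise ValueError(f"missing values in covariate {cov!r}")
        v = demo[cov]
        if v.dtype.kind in "if":
            cols.append(v.to_numpy(dtype=float))
        else:
            levels = sorted(v.unique())
            for lev in levels[1:]:          # first level is the reference
                cols.append((v == lev).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(demo), 0))
    return np.column_stack(cols)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ss, n, a_prior, b_prior):
    return (0.5 * ss + b_prior) / (n / 2.0 + a_prior - 1.0)


def _it_solve(s_data, g_hat, d_hat, g_bar, t2, a_prior, b_prior,
              conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the conditional posterior means (parametric EB)."""
    n = np.sum(~np.isnan(s_data), axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ss = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(ss, n, a_prior, b_prior)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)))
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m ** 2) / max(s2, 1e-12)


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m ** 3) / max(s2, 1e-12)


def combat(data: np.ndarray, batch: np.ndarray, design: np.ndarray,
           shrinkage: bool = True, fit_mask: np.ndarray | None = None
           ) -> np.ndarray:
    """Harmonize a features-by-samples matrix.

    Parameters
    ----------
    data : (G, N) matrix, one row per feature (ROI), one column per subject.
    batch : length-N batch labels.
    design : (N, P) covariate design (no intercept, no batch columns).
    shrinkage : empirical-Bayes shrinkage of batch parameters across
        features; with ``False`` the per-feature estimates are used directly
        (the large-n / no-pooling limit).
    fit_mask : optional boolean length-N mask selecting the reference
        subjects (e.g. healthy controls) on which batch parameters are
        estimated; the adjustment is then applied to all subjects.  This
        keeps disease effects out of the batch estimates.
    """
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    levels, b_idx = np.unique(batch, return_inverse=True)
    if fit_mask is None:
        fit_mask = np.ones(data.shape[1], dtype=bool)
    else:
        fit_mask = np.asarray(fit_mask, dtype=bool)
    counts_fit = np.bincount(b_idx[fit_mask], minlength=len(levels))
    if np.any(counts_fit < 2):
        bad = levels[counts_fit < 2]
        raise ValueError(f"batches with fewer than 2 reference subjects: {list(bad)}")
    if len(levels) == 1:
        return data.copy()

    G, N = data.shape
    onehot = np.eye(len(levels))[b_idx]                       # N x B
    X = np.hstack([onehot, design])                           # N x (B+P)
    beta, *_ = np.linalg.lstsq(X[fit_mask], data[:, fit_mask].T, rcond=None)
    batch_coef, cov_coef = beta[:len(levels)], beta[len(levels):]

    grand_mean = (counts_fit / counts_fit.sum()) @ batch_coef  # G
    cov_part = (design @ cov_coef).T if design.size else np.zeros((G, N))
    stand_mean = grand_mean[:, None] + cov_part
    resid = data[:, fit_mask] - (X[fit_mask] @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-24)
    s_data = (data - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = s_data.copy()
    for i, lev in enumerate(levels):
        cols = b_idx == i
        sb_fit = s_data[:, cols & fit_mask]
        g_hat = sb_fit.mean(axis=1)
        d_hat = sb_fit.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        if shrinkage and G > 1:
            g_bar, t2 = g_hat.mean(), g_hat.var()
            t2 = max(t2, 1e-12)
            g_star, d_star = _it_solve(sb_fit, g_hat, d_hat, g_bar, t2,
                                       _aprior(d_hat), _bprior(d_hat))
        else:
            g_star, d_star = g_hat, d_hat
        adjusted[:, cols] = (s_data[:, cols] - g_star[:, None]) \
            / np.sqrt(d_star)[:, None]

    return adjusted * np.sqrt(var_pooled)[:, None] + stand_mean


def harmonize_batches(table: pd.DataFrame, covariates: tuple[str, ...] = ("age", "sex"),
                      shrinkage: bool = True,
                      reference_subjects: "set[str] | None" = None) -> pd.DataFrame:
    """Harmonize a long-format regional feature table across its batches.

    The table needs columns subject_id, roi_id, value, batch and the
    requested covariates (plus band for iEEG).  Returns a copy with
    harmonized values; a single-batch table is returned unchanged.  When
    ``reference_subjects`` is given (typically the controls), batch
    parameters are estimated on those subjects only and applied to everyone.
    """
    for col in ("subject_id", "roi_id", "value", "batch"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    keys = [k for k in _FEATURE_KEYS if k in table.columns and table[k].notna().any()]
    wide = table.pivot_table(index=keys, columns="subject_id", values="value",
                             aggfunc="first", sort=True)
    if wide.isna().any().any():
        raise ValueError("feature table is not complete per (subject, roi[, band])")
    demo = (table.drop_duplicates("subject_id").set_index("subject_id")
            .loc[wide.columns])
    if demo["batch"].nunique() == 1:
        return table.copy()
    X = _design(demo.reset_index(), tuple(covariates))
    fit_mask = None
    if reference_subjects is not None:
        fit_mask = wide.columns.isin(list(reference_subjects))
    adj = combat(wide.to_numpy(), demo["batch"].to_numpy(), X,
                 shrinkage=shrinkage, fit_mask=fit_mask)
    wide_adj = pd.DataFrame(adj, index=wide.index, columns=wide.columns)
    long_adj = wide_adj.stack().rename("value").reset_index()
    out = table.drop(columns="value").merge(long_adj, on=keys + ["subject_id"],
                                            how="left")
    return out[table.columns]
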