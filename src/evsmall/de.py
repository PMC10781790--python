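"""Covariate-adjusted, empirical-Bayes moderated differential expression.

Per-feature ordinary least squares on log2(normalized + 1) against an
intercept, a two-group contrast indicator, and optional sex/batch covariates;
residual variances are shrunk toward a scaled-inverse-chi-square prior whose
hyperparameters (d0, s0^2) are estimated by method of moments on
log residual variances (the digamma/trigamma identities of the moderated-t
framework). Calls use the raw-p threshold (p < 0.05) together with a strict
1.4-fold-change floor; BH-adjusted p values are reported alongside, with an
optional switch to call on adjusted p instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

P_THRESHOLD = 0.05
FC_THRESHOLD = 1.4


@dataclass
class DesignSpec:
    """Two-group contrast with optional covariates.

    ``contrast = (A, B)`` tests A versus B; log2fc > 0 means higher in A.
    """

    contrast: tuple[str, str]
    covariates: tuple[str, ...] = ()
    log_offset: float = 1.0


def log_transform(normalized: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """y = log2(normalized + offset)."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("negative counts cannot be log-transformed")
    return np.log2(normalized + offset)


def _design_matrix(metadata: pd.DataFrame, design: DesignSpec) -> tuple[pd.DataFrame, list[str]]:
    a, b = design.contrast
    groups = metadata["group"]
    keep = groups.isin([a, b])
    meta = metadata.loc[keep]
    cols = {"intercept": np.ones(len(meta)), "contrast": (meta["group"] == a).astype(float)}
    for cov in design.covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        values = meta[cov]
        if values.dtype.kind in "biufc":
            cols[cov] = values.astype(float)
        else:
            levels = sorted(values.unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (values == lev).astype(float)
    X = pd.DataFrame(cols, index=meta.index)
    return X, list(meta.index)


@dataclass
class LinearFit:
    """Per-feature OLS results for the contrast coefficient."""

    feature_ids: list[str]
    coef: np.ndarray  # contrast coefficient == log2 fold change
    s2: np.ndarray  # residual variance
    df_residual: int
    stdev_unscaled: float  # sqrt((X'X)^-1 [contrast, contrast])
    mean_expression: np.ndarray  # A-value: mean log2 expression


def fit_linear_models(
    expression: pd.DataFrame, metadata: pd.DataFrame, design: DesignSpec
) -> LinearFit:
    """OLS per feature: intercept + contrast indicator + covariates."""
    X, sample_ids = _design_matrix(metadata, design)
    Y = expression[sample_ids].to_numpy(dtype=float)  # features x samples
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # identify offending columns by incremental rank
        bad = []
        cur = np.empty((n, 0))
        for j, name in enumerate(X.columns):
            cand = np.hstack([cur, Xm[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    beta = xtx_inv @ Xm.T @ Y.T  # p x features
    resid = Y.T - Xm @ beta
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=0) / df
    c = list(X.columns).index("contrast")
    return LinearFit(
        feature_ids=list(expression.index),
        coef=beta[c],
        s2=s2,
        df_residual=df,
        stdev_unscaled=math.sqrt(xtx_inv[c, c]),
        mean_expression=Y.mean(axis=1),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_statistics(
    coef: np.ndarray,
    s2: np.ndarray,
    df_residual: float,
    d0: float,
    s0_squared: float,
    stdev_unscaled: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Posterior variances, moderated t and two-sided p for given (d0, s0^2).

    s2_post = (d0*s0^2 + d*s^2) / (d0 + d); t = coef / (s_post * SE);
    p from t with d0 + d df (normal when d0 is infinite). As d0 -> 0 the
    statistics reduce to the ordinary t.
    """
    s2 = np.asarray(s2, dtype=float)
    d = float(df_residual)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_squared)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_squared + d * s2) / (d0 + d)
        df_total = d0 + d
    t = coef / (np.sqrt(s2_post) * stdev_unscaled)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return s2_post, t, p, df_total


@dataclass
class ModerationResult:
    d0: float  # prior degrees of freedom (may be inf)
    s0_squared: float  # prior variance
    s2_post: np.ndarray  # posterior (moderated) variances
    t: np.ndarray
    p: np.ndarray
    df_total: float


def ebayes_moderate(
    s2: np.ndarray, df_residual: int, coef: np.ndarray, stdev_unscaled: float
) -> ModerationResult:
    """Empirical-Bayes variance moderation and moderated t statistics.

    Fits the scaled-inverse-chi-square prior to the observed residual
    variances by method of moments on z = log(s^2): under the model,
    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - (digamma(d0/2) - log(d0/2))
    and Var[z] = trigamma(d/2) + trigamma(d0/2). Features with s^2 = 0 are
    excluded from estimation and receive the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.sum(s2 > 0) < 10:
        raise ValueError("need >= 10 features with positive residual variance")
    d = float(df_residual)
    pos = s2 > 0
    z = np.log(s2[pos])
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(
            e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
    else:
        # variances less dispersed than pure chi-square noise: infinite prior
        # df; the natural limit estimator of the common variance is the pooled
        # mean, which makes moderation an exact no-op on identical variances
        d0 = math.inf
        s0_sq = float(np.mean(s2[pos]))

    s2_post, t, p, df_total = moderated_statistics(
        coef, s2, d, d0, s0_sq, stdev_unscaled
    )
    return ModerationResult(
        d0=d0, s0_squared=s0_sq, s2_post=s2_post, t=t, p=p, df_total=df_total
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_differential(
    log2fc: np.ndarray,
    p: np.ndarray,
    p_adj: np.ndarray | None = None,
    use_adjusted: bool = False,
) -> np.ndarray:
    """up/down/ns calls: p < 0.05 and fold change strictly > 1.4."""
    pvals = p_adj if use_adjusted else p
    if pvals is None:
        raise ValueError("adjusted p values required when use_adjusted=True")
    fc = 2.0 ** np.asarray(log2fc, dtype=float)
    calls = np.full(len(pvals), "ns", dtype=object)
    sig = np.asarray(pvals) < P_THRESHOLD
    calls[sig & (fc > FC_THRESHOLD)] = "up"
    calls[sig & (1.0 / fc > FC_THRESHOLD)] = "down"
    return calls


def differential_expression(
    normalized: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = (),
    log_offset: float = 1.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Full DE table for one contrast.

    Returns a DataFrame indexed by feature with columns log2fc, A (mean log2
    expression), t, p, p_adj, call.
    """
    design = DesignSpec(contrast=contrast, covariates=covariates, log_offset=log_offset)
    expr = log_transform(normalized, offset=log_offset)
    fit = fit_linear_models(expr, metadata, design)
    mod = ebayes_moderate(fit.s2, fit.df_residual, fit.coef, fit.stdev_unscaled)
    p_adj = bh_adjust(mod.p)
    calls = call_differential(fit.coef, mod.p, p_adj, use_adjusted=use_adjusted)
    return pd.DataFrame(
        {
            "log2fc": fit.coef,
            "A": fit.mean_expression,
            "t": mod.t,
            "p": mod.p,
            "p_adj": p_adj,
            "call": calls,
        },
        index=fit.feature_ids,
    )
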