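"""iRBD phenoconversion survival analysis.

Per-miRNA age/sex-adjusted univariate Cox proportional-hazards screening
(Efron tie handling, via lifelines), selection of candidates at Wald p < 0.05,
optimal-cutpoint dichotomization by the maximally selected log-rank statistic,
and Kaplan-Meier curves with log-rank tests.

Features are standardized to unit SD before the Cox fit, so hazard ratios are
per standard deviation of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoxResult:
    feature_id: str
    beta: float  # log hazard ratio per SD
    hr: float
    se: float
    p: float
    adjusted: bool  # age/sex in the model
    reliable: bool = True  # False when the fit needed a ridge fallback


def _encode(records: pd.DataFrame, feature: str, covariates) -> pd.DataFrame:
    df = records[["time", "event"]].copy()
    x = records[feature].astype(float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    df[feature] = (x - x.mean()) / sd
    for cov in covariates:
        if cov == "sex":
            df["sex"] = (records["sex"] == "M").astype(float)
        else:
            df[cov] = records[cov].astype(float)
    return df


def cox_univariate_adjusted(
    records: pd.DataFrame, feature: str, covariates=("age", "sex")
) -> CoxResult:
    """Cox PH fit of one standardized miRNA plus age/sex confounders.

    Requires >= 2 events. Monotone-likelihood fits (perfect separation) fall
    back to a small ridge penalty and are flagged unreliable.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if records["event"].sum() < 2:
        raise ValueError(">=2 events required")
    df = _encode(records, feature, covariates)
    for penalizer, reliable in ((0.0, True), (0.1, False)):
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
        beta = float(cph.params_[feature])
        se = float(cph.standard_errors_[feature])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 20:
            continue  # monotone likelihood: retry penalized
        return CoxResult(
            feature_id=feature,
            beta=beta,
            hr=float(np.exp(beta)),
            se=se,
            p=float(cph.summary.loc[feature, "p"]),
            adjusted=bool(covariates),
            reliable=reliable,
        )
    raise RuntimeError(f"Cox fit failed for {feature!r}")


def cox_screen(
    records: pd.DataFrame, features: list[str], covariates=("age", "sex")
) -> pd.DataFrame:
    """Univariate adjusted Cox fit per feature; table indexed by feature."""
    rows = []
    for feat in features:
        res = cox_univariate_adjusted(records, feat, covariates)
        rows.append(
            {
                "feature": feat,
                "beta": res.beta,
                "HR": res.hr,
                "se": res.se,
                "p": res.p,
                "reliable": res.reliable,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def select_candidates(cox_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Features with Wald p strictly below alpha, ascending p."""
    hits = cox_table[cox_table["p"] < alpha].sort_values("p")
    return list(hits.index)


# --------------------------------------------------------------------------
# Log-rank and Kaplan-Meier (in-package; standardized statistic needed for
# the maximally selected cutpoint search)
# --------------------------------------------------------------------------


def logrank_statistic(time, event, group) -> tuple[float, float, float]:
    """Two-group log-rank test.

    Returns (z, chi2, p): z is the standardized observed-minus-expected
    statistic for group 1 (positive when group 1 has more events than
    expected, i.e. worse survival), chi2 = z**2 with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    obs = exp = var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & (group == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 0.0, 1.0
    z = (obs - exp) / np.sqrt(var)
    chi2 = z * z
    return float(z), float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival curve: S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Returns a step table (time, at_risk, events, survival) starting at
    (0, n, 0, 1); rows at every distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    rows = [{"time": 0.0, "at_risk": n, "events": 0, "survival": 1.0}]
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows)


def km_by_group(records: pd.DataFrame, grouping: pd.Series) -> dict[object, pd.DataFrame]:
    """KM curve per group of ``grouping`` (indexed like records)."""
    out = {}
    for g in grouping.unique():
        ids = grouping.index[grouping == g]
        sub = records.loc[ids]
        out[g] = km_estimate(sub["time"], sub["event"])
    return out


# --------------------------------------------------------------------------
# Maximally selected cutpoint
# --------------------------------------------------------------------------


@dataclass
class CutpointResult:
    feature_id: str
    cutpoint: float
    statistic: float  # standardized log-rank z at the cutpoint (|max|)
    n_high: int
    n_low: int
    logrank_p: float  # naive p at the selected cutpoint (anti-conservative)


def optimal_cutpoint(
    records: pd.DataFrame, feature: str, minprop: float = 0.1
) -> CutpointResult:
    """Best high/low dichotomization by maximally selected log-rank statistic.

    Candidate cutpoints are midpoints between consecutive distinct feature
    values whose low-group proportion lies in [minprop, 1 - minprop]; the
    cutpoint maximizing |standardized log-rank statistic| wins. The reported
    p value is NOT adjusted for the maximal selection and is anti-conservative.
    """
    if records["event"].sum() < 2:
        raise ValueError(">=2 events required")
    x = records[feature].to_numpy(dtype=float)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    values = np.unique(x)
    if len(values) < 2:
        raise ValueError(f"feature {feature!r} has no admissible cutpoint")
    n = len(x)
    best = None
    for lo, hi in zip(values[:-1], values[1:]):
        cut = 0.5 * (lo + hi)
        prop_low = np.mean(x <= cut)
        if not (minprop <= prop_low <= 1.0 - minprop):
            continue
        group = (x > cut).astype(int)  # 1 = high expression
        z, _, p = logrank_statistic(time, event, group)
        if best is None or abs(z) > abs(best[1]):
            best = (cut, z, p, int(group.sum()), int(n - group.sum()))
    if best is None:
        raise ValueError(f"no admissible cutpoint for {feature!r} at minprop={minprop}")
    cut, z, p, n_high, n_low = best
    return CutpointResult(
        feature_id=feature,
        cutpoint=cut,
        statistic=z,
        n_high=n_high,
        n_low=n_low,
        logrank_p=p,
    )


def conversion_analysis(
    records: pd.DataFrame,
    features: list[str],
    covariates=("age", "sex"),
    alpha: float = 0.05,
    minprop: float = 0.1,
):
    """Cox screen -> candidate selection -> cutpoint + KM per candidate.

    Returns (cox table, candidate list, {feature: (CutpointResult, KM curves
    dict with 'high'/'low' keys)}).
    """
    cox_table = cox_screen(records, features, covariates)
    candidates = select_candidates(cox_table, alpha=alpha)
    km_results = {}
    for feat in candidates:
        cp = optimal_cutpoint(records, feat, minprop=minprop)
        grouping = pd.Series(
            np.where(records[feat] > cp.cutpoint, "high", "low"), index=records.index
        )
        km_results[feat] = (cp, km_by_group(records, grouping))
    return cox_table, candidates, km_results
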