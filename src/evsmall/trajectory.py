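"""Expression-pattern discovery across the healthy -> iRBD -> PD hierarchy.

Features passing a Kruskal-Wallis screen (p < 0.05 across the three groups)
are summarized as standardized 3-point group-mean profiles and soft-clustered
with fuzzy c-means (the Mfuzz model: Euclidean distance, fuzzifier m > 1,
membership-weighted centers). Cluster centers strictly ordered along the
group hierarchy are labeled increasing / decreasing; everything else "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUP_ORDER = ("healthy", "iRBD", "PD")


# --------------------------------------------------------------------------
# Screening and profiles
# --------------------------------------------------------------------------


def kruskal_wallis_screen(
    normalized: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    group_order=GROUP_ORDER,
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis test across the three groups.

    Returns a DataFrame indexed by feature with the per-group means, the
    tie-corrected H statistic, kw_p, and a ``significant`` flag (strict <).
    Features with all values tied get p = 1 (never significant).
    """
    present = [g for g in group_order if (groups == g).any()]
    if len(present) < 3:
        raise ValueError("need all three groups for the screen")
    sample_groups = [normalized.columns[groups[normalized.columns] == g] for g in present]
    if any(len(ids) < 2 for ids in sample_groups):
        raise ValueError("every group needs >= 2 samples")
    rows = []
    for feat, values in normalized.iterrows():
        parts = [values[ids].to_numpy(dtype=float) for ids in sample_groups]
        flat = np.concatenate(parts)
        if np.all(flat == flat[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*parts)
        row = {"kw_h": float(h), "kw_p": float(p)}
        for g, part in zip(present, parts):
            row[f"mean_{g}"] = float(part.mean())
        rows.append(row)
    out = pd.DataFrame(rows, index=normalized.index)
    out["significant"] = out["kw_p"] < alpha
    return out


def standardize_profiles(group_means: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize 3-point profiles to mean 0, population sd 1.

    Constant profiles are excluded (they carry no shape information).
    Columns must be ordered (healthy, iRBD, PD).
    """
    values = group_means.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    standardized = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]
    return pd.DataFrame(
        standardized, index=group_means.index[keep], columns=group_means.columns
    )


# --------------------------------------------------------------------------
# Fuzzy c-means
# --------------------------------------------------------------------------


@dataclass
class FuzzyClusterModel:
    k: int
    m: float
    centers: np.ndarray  # k x d
    memberships: pd.DataFrame  # features x k
    objective: float
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0

    def harden(self) -> pd.Series:
        """Assign each feature to its maximum-membership cluster."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1), index=self.memberships.index
        )


def _memberships_from_centers(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    coincident = zero.any(axis=1)
    if coincident.any():
        # limit convention: membership 1 at the coincident center
        rows = np.flatnonzero(coincident)
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    rest = ~coincident
    if rest.any():
        power = 1.0 / (m - 1.0)
        inv = d2[rest] ** -power
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _objective(X, centers, u, m) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u**m) * d2).sum())


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int = 8,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
    restarts: int = 10,
) -> FuzzyClusterModel:
    """Fuzzy c-means on standardized profiles (Euclidean distance).

    Alternates membership and center updates from random center
    initializations; keeps the best of ``restarts`` runs by final objective.
    Convergence: maximum center shift < tol.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best: FuzzyClusterModel | None = None
    for _ in range(max(restarts, 1)):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        centers = centers + rng.normal(scale=1e-6, size=centers.shape)
        history: list[float] = []
        for it in range(max_iter):
            u = _memberships_from_centers(X, centers, m)
            um = u**m
            denom = um.sum(axis=0)
            new_centers = np.where(
                denom[:, None] > 0, (um.T @ X) / np.maximum(denom[:, None], 1e-300), centers
            )
            history.append(_objective(X, new_centers, u, m))
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        u = _memberships_from_centers(X, centers, m)
        obj = _objective(X, centers, u, m)
        if best is None or obj < best.objective:
            best = FuzzyClusterModel(
                k=k,
                m=m,
                centers=centers,
                memberships=pd.DataFrame(
                    u, index=profiles.index, columns=[f"cluster{j + 1}" for j in range(k)]
                ),
                objective=obj,
                objective_history=history,
                n_iter=it + 1,
            )
    return best


# --------------------------------------------------------------------------
# Pattern calling
# --------------------------------------------------------------------------


def assign_patterns(model: FuzzyClusterModel) -> tuple[dict[int, str], pd.DataFrame]:
    """Label each cluster by its center's shape along (healthy, iRBD, PD).

    increasing iff center_H < center_R < center_P strictly; decreasing iff
    strictly reversed; otherwise "other". Returns (cluster labels, per-feature
    table with hardened cluster, its membership, and the pattern label).
    """
    labels: dict[int, str] = {}
    for j, c in enumerate(model.centers):
        if c[0] < c[1] < c[2]:
            labels[j] = "increasing"
        elif c[0] > c[1] > c[2]:
            labels[j] = "decreasing"
        else:
            labels[j] = "other"
    hard = model.harden()
    u = model.memberships.to_numpy()
    table = pd.DataFrame(
        {
            "cluster": hard + 1,
            "membership": u[np.arange(len(hard)), hard.to_numpy()],
            "pattern": [labels[c] for c in hard],
        },
        index=model.memberships.index,
    )
    return labels, table


def trajectory_analysis(
    normalized: pd.DataFrame,
    groups: pd.Series,
    k: int = 8,
    m: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, FuzzyClusterModel, pd.DataFrame]:
    """Screen -> standardize -> cluster -> label, end to end.

    Returns (screen table, fitted model, per-feature cluster/pattern table).
    """
    screen = kruskal_wallis_screen(normalized, groups, alpha=alpha)
    sig = screen[screen["significant"]]
    means = sig[[f"mean_{g}" for g in GROUP_ORDER]]
    profiles = standardize_profiles(means)
    model = fuzzy_cmeans(profiles, k=k, m=m, seed=seed)
    _, table = assign_patterns(model)
    return screen, model, table
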