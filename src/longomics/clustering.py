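"""Fuzzy c-means clustering of event-response trajectories.

Significant features from the deviation test are summarised as
category-wise mean trajectories over the ordered event states (preH,
EE, EL, RE, postH), z-scored per feature, and clustered with fuzzy
c-means so that each feature receives a graded membership in every
temporal pattern. The cluster count is chosen by the elbow of the
objective-vs-c curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EVENT_CATEGORIES


def trajectory_matrix(
    corrected_means: pd.DataFrame, significant_features=None
) -> pd.DataFrame:
    """Feature x category z-scored trajectories.

    ``corrected_means`` holds one row per feature and one column per
    ordered category (preH, EE, EL, RE, postH), e.g. per-category means
    of baseline-corrected values (preH/postH entries are the corrected
    baseline means, typically ~0). Missing categories are imputed from
    the adjacent categories and flagged via the ``imputed`` attribute.
    Rows are z-scored across categories; flat rows come back as zeros.
    """
    cats = [c for c in EVENT_CATEGORIES if c in corrected_means.columns]
    if len(cats) < 3:
        raise ValueError("need at least 3 ordered categories")
    M = corrected_means[cats].copy()
    if significant_features is not None:
        M = M.loc[[f for f in significant_features if f in M.index]]
    imputed = []
    vals = M.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.isnan(row).any():
            imputed.append(M.index[i])
            idx = np.arange(len(row))
            ok = np.isfinite(row)
            if ok.sum() == 0:
                raise ValueError(f"feature {M.index[i]!r} has no category means")
            vals[i] = np.interp(idx, idx[ok], row[ok])
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out = pd.DataFrame(z, index=M.index, columns=cats)
    out.attrs["imputed"] = imputed
    return out


def _fcm_objective(X, centers, m):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-300)
    u = _memberships(d2, m)
    return float(np.sum(u**m * d2)), u


def _memberships(d2, m):
    power = 1.0 / (m - 1.0)
    inv = d2 ** (-power)
    return inv / inv.sum(axis=1, keepdims=True)


@dataclass
class FuzzyCMeans:
    """Standard fuzzy c-means with alternating membership/center updates.

    Parameters: cluster count ``c`` (>= 2), fuzzifier ``m`` (> 1,
    default 2), convergence tolerance on the center shift, iteration cap
    and an init seed.
    """

    trajectories: pd.DataFrame
    c: int
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.c > len(self.trajectories) - 1:
            raise ValueError("c must be <= n_features - 1")

    def fit(self) -> "ClusterModel":
        X = self.trajectories.to_numpy(dtype=float)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        centers = X[rng.choice(n, self.c, replace=False)].copy()
        converged = False
        trace: list[float] = []
        for _ in range(self.max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-300)
            u = _memberships(d2, self.m)
            um = u**self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            trace.append(float(np.sum(um * d2)))
            if shift < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("fuzzy c-means did not converge; returning best iterate")
        d2 = np.maximum(((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 1e-300)
        u = _memberships(d2, self.m)
        return ClusterModel(
            c=self.c,
            m=self.m,
            centers=pd.DataFrame(centers, columns=self.trajectories.columns),
            memberships=pd.DataFrame(
                u,
                index=self.trajectories.index,
                columns=[f"cluster_{k}" for k in range(self.c)],
            ),
            objective=float(np.sum((u**self.m) * d2)),
            converged=converged,
            objective_trace=trace,
        )


@dataclass
class ClusterModel:
    c: int
    m: float
    centers: pd.DataFrame
    memberships: pd.DataFrame
    objective: float
    converged: bool = True
    objective_trace: list = field(default_factory=list)

    def hard_labels(self) -> pd.Series:
        return self.memberships.idxmax(axis=1)

    def summary(self) -> str:
        sizes = self.hard_labels().value_counts().sort_index()
        lines = [
            f"Fuzzy c-means: c = {self.c}, m = {self.m:g}, objective = {self.objective:.4g}"
            + ("" if self.converged else " (not converged)"),
            "hard cluster sizes: " + ", ".join(f"{k}={v}" for k, v in sizes.items()),
        ]
        return "\n".join(lines)


def elbow_select(
    trajectories: pd.DataFrame,
    c_range=None,
    m: float = 2.0,
    seed: int = 0,
) -> int:
    """Pick the cluster count at the elbow of the objective-vs-c curve.

    The elbow is the c with maximum curvature (largest positive second
    difference of the objective), with the c = 1 objective (total squared
    distance to the global centroid) anchoring the curve so that c = 2
    can be selected. A flat curve falls back to the smallest c with a
    warning.
    """
    n = len(trajectories)
    if c_range is None:
        c_range = range(2, min(9, n - 1))
    cs = sorted(c_range)
    if not cs or cs[0] < 2 or cs[-1] > n - 1:
        raise ValueError("c_range must lie within [2, n_features - 1]")
    X = trajectories.to_numpy(dtype=float)
    sse1 = float(((X - X.mean(axis=0)) ** 2).sum())
    curve_c = [1] + cs
    objs = [sse1]
    for c in cs:
        fit = FuzzyCMeans(trajectories, c=c, m=m, seed=seed).fit()
        # hard-assignment SSE puts all c on the same scale as the c=1 anchor
        centers = fit.centers.to_numpy(dtype=float)
        lab = fit.memberships.to_numpy().argmax(axis=1)
        objs.append(float(((X - centers[lab]) ** 2).sum()))
    objs = np.asarray(objs)
    if len(curve_c) < 3 or np.allclose(objs, objs[0]):
        warnings.warn("objective curve is flat; selecting the smallest c")
        return cs[0]
    curvature = objs[:-2] - 2 * objs[1:-1] + objs[2:]
    return curve_c[1 + int(np.argmax(curvature))]
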