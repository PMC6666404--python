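"""Association networks within and between individuals.

Two complementary correlation designs avoid Simpson's paradox in
repeated-measures cohorts: the repeated-measures correlation (rmcorr)
estimates the common within-subject association by fitting parallel
lines with per-subject intercepts, while the between-individual design
collapses each subject to the median of their healthy visits and uses
partial correlation corrected for BMI, age and sex.

Microbiome data are compositional, so taxon-taxon and taxon-host edges
use either the centred log-ratio transform followed by rmcorr, or the
SparCC basis-correlation estimator, which infers correlations of the
unobserved absolute abundances from log-ratio variances under a
sparsity assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix, SubjectPhenotype, VisitMetadata


def _fisher_ci(r: float, se: float) -> tuple[float, float]:
    r = min(max(r, -1 + 1e-15), 1 - 1e-15)
    z = np.arctanh(r)
    return float(np.tanh(z - 1.959963984540054 * se)), float(np.tanh(z + 1.959963984540054 * se))


def rmcorr(x, y, subjects) -> dict:
    """Repeated-measures correlation: common within-subject association.

    Equivalent to an analysis of covariance with subject as a factor and
    a common slope: r_rm = sign(slope) * sqrt(SS_measure / (SS_measure +
    SS_error)), with df = N - k - 1 for k subjects and p from
    F(1, df). The 95% CI uses the Fisher z transform with
    SE = 1/sqrt(df - 1).
    """
    df_in = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float), "s": subjects})
    df_in = df_in.dropna()
    counts = df_in.groupby("s").size()
    keep = counts[counts >= 2].index
    df_in = df_in[df_in["s"].isin(keep)]
    if df_in["s"].nunique() < 2:
        raise ValueError("need >=2 subjects with >=2 paired observations")
    xc = df_in["x"] - df_in.groupby("s")["x"].transform("mean")
    yc = df_in["y"] - df_in.groupby("s")["y"].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variation in x or y")
    sxy = float((xc * yc).sum())
    r = sxy / np.sqrt(sxx * syy)
    n = len(df_in)
    k = df_in["s"].nunique()
    dof = n - k - 1
    if dof < 1:
        raise ValueError("insufficient degrees of freedom")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        F = (r * r) / (1 - r * r) * dof
        p = float(stats.f.sf(F, 1, dof))
    se = 1.0 / np.sqrt(dof - 1) if dof > 1 else np.inf
    return {"r": r, "df": dof, "p": p, "ci": _fisher_ci(r, se), "n_obs": n, "method": "rmcorr"}


def partial_correlation(x, y, covariates=None) -> dict:
    """Pearson correlation of x and y after removing linear covariate effects.

    Both variables are residualised on the covariates (with intercept);
    p comes from the t distribution with n - 2 - p_cov degrees of
    freedom. With no covariates this is exactly the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    n = len(x)
    p_cov = C.shape[1]
    if n < p_cov + 4:
        raise ValueError("need at least p_covariates + 4 complete observations")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    H = Z @ np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)[0]
    rx, ry = x - H[:, 0], y - H[:, 1]
    # a variable fully explained by the covariates has nothing left to correlate
    tiny_x = np.sum(rx**2) <= 1e-12 * max(np.sum((x - x.mean()) ** 2), 1e-300)
    tiny_y = np.sum(ry**2) <= 1e-12 * max(np.sum((y - y.mean()) ** 2), 1e-300)
    dof0 = n - 2 - p_cov
    if tiny_x or tiny_y:
        return {"r": 0.0, "df": dof0, "p": 1.0, "ci": (-1.0, 1.0), "n_obs": n, "method": "partial"}
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    dof = n - 2 - p_cov
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), dof))
    se = 1.0 / np.sqrt(n - p_cov - 3) if n - p_cov - 3 > 0 else np.inf
    return {"r": r, "df": dof, "p": p, "ci": _fisher_ci(r, se), "n_obs": n, "method": "partial"}


def _subject_medians(matrix: OmicsMatrix, metadata: VisitMetadata) -> pd.DataFrame:
    """Per-subject medians over healthy visits (subjects x features)."""
    healthy = metadata.healthy()
    cols = [s for s in healthy["sample_id"] if s in matrix.sample_ids]
    subj_of = healthy.set_index("sample_id")["subject_id"].reindex(cols)
    return matrix.data[cols].T.groupby(subj_of).median()


def sspg_association(
    matrix: OmicsMatrix,
    metadata: VisitMetadata,
    phenotypes: SubjectPhenotype,
    target: str = "sspg",
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Screen per-subject healthy medians against SSPG (or the IR/IS dummy).

    Partial correlation corrected for BMI, age and sex; BH adjustment
    within the screen; rows with q below the threshold are marked
    significant.
    """
    from .events import fdr_adjust

    medians = _subject_medians(matrix, metadata)
    ph = phenotypes.table.set_index("subject_id").reindex(medians.index)
    if target == "sspg":
        yv = ph["sspg"]
    elif target == "ir_is":
        yv = ph["ir_is"].map({"IS": 0.0, "IR": 1.0})
    else:
        raise ValueError("target must be 'sspg' or 'ir_is'")
    sex = ph["sex"].map({"F": 0.0, "M": 1.0})
    cov = np.column_stack([ph["bmi"], ph["age"], sex])
    ok = yv.notna().to_numpy()
    if ok.sum() < 10:
        import warnings

        warnings.warn("fewer than 10 subjects with SSPG; screen is underpowered")
    records = []
    for feat in medians.columns:
        try:
            res = partial_correlation(medians[feat].to_numpy()[ok], yv.to_numpy(dtype=float)[ok], cov[ok])
        except ValueError:
            continue
        records.append({"feature": feat, "r": res["r"], "p": res["p"], "n": res["n_obs"]})
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = fdr_adjust(table["p"].clip(lower=np.finfo(float).tiny))
        table["significant"] = table["q"] < q_threshold
    return table


# -- SparCC --------------------------------------------------------------------

def _logratio_variances(frac: np.ndarray) -> np.ndarray:
    """t_ij = Var(log(f_i / f_j)) over samples, for all taxon pairs."""
    logf = np.log(frac)
    v = logf.var(axis=1, ddof=1)
    cov = np.cov(logf)
    return v[:, None] + v[None, :] - 2 * cov


def _basis_correlations(T: np.ndarray, kept: np.ndarray, var_floor: float = 1e-8):
    """Solve the sparse linear system for basis variances and correlations.

    ``kept[i, j]`` marks pairs whose log-ratio variance still enters
    taxon i's equation (strongly correlated pairs get excluded
    iteratively). Negative basis-variance solutions are clamped to a
    small positive floor.
    """
    D = T.shape[0]
    M = kept.astype(float)
    np.fill_diagonal(M, 0.0)
    deg = M.sum(axis=1)
    A = M.copy()
    A[np.diag_indices(D)] = deg
    t = (T * M).sum(axis=1)
    omega = np.linalg.solve(A, t)
    omega = np.maximum(omega, var_floor)
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - T) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0), omega


def _sparcc_once(frac: np.ndarray, n_exclude_iter: int, threshold: float) -> np.ndarray:
    D = frac.shape[0]
    T = _logratio_variances(frac)
    kept = np.ones((D, D), dtype=bool)
    np.fill_diagonal(kept, False)
    rho, _ = _basis_correlations(T, kept)
    for _ in range(n_exclude_iter):
        masked = np.where(kept, np.abs(np.triu(rho, 1)), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        # never let a taxon's equation drop below 3 partners
        if kept[i].sum() <= 3 or kept[j].sum() <= 3:
            break
        kept[i, j] = kept[j, i] = False
        rho, _ = _basis_correlations(T, kept)
    return rho


@dataclass
class SparCC:
    """Basis-correlation estimation for one taxonomic rank's count table.

    Counts (taxa x samples) are converted to fractions by Dirichlet
    posterior draws (pseudocount 1); the estimate is the median over
    ``n_iter`` such draws, each refined by up to ``n_exclude_iter``
    exclusions of the most strongly correlated pair above
    ``exclusion_threshold``. Edge p-values come from ``n_bootstrap``
    null datasets built by permuting each taxon's counts independently.
    """

    counts: pd.DataFrame
    n_iter: int = 20
    n_exclude_iter: int = 10
    exclusion_threshold: float = 0.1
    n_bootstrap: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 4:
            raise ValueError("SparCC needs >= 4 taxa (basis system underdetermined)")

    def _estimate(self, counts: np.ndarray, rng) -> np.ndarray:
        D = counts.shape[0]
        est = np.empty((self.n_iter, D, D))
        for it in range(self.n_iter):
            frac = np.column_stack(
                [rng.dirichlet(counts[:, s] + 1.0) for s in range(counts.shape[1])]
            )
            est[it] = _sparcc_once(frac, self.n_exclude_iter, self.exclusion_threshold)
        return np.median(est, axis=0)

    def fit(self) -> "SparCCResults":
        rng = np.random.default_rng(self.seed)
        counts = self.counts.to_numpy(dtype=float)
        rho = self._estimate(counts, rng)
        taxa = list(self.counts.index)
        pvals = None
        if self.n_bootstrap > 0:
            exceed = np.zeros_like(rho)
            for _ in range(self.n_bootstrap):
                perm = np.empty_like(counts)
                for i in range(counts.shape[0]):
                    perm[i] = rng.permutation(counts[i])
                null_rho = self._estimate(perm, rng)
                exceed += np.abs(null_rho) >= np.abs(rho)
            pvals = (exceed + 1.0) / (self.n_bootstrap + 1.0)
            np.fill_diagonal(pvals, np.nan)
            pvals = pd.DataFrame(pvals, index=taxa, columns=taxa)
        return SparCCResults(
            correlations=pd.DataFrame(rho, index=taxa, columns=taxa), pvalues=pvals
        )


@dataclass
class SparCCResults:
    correlations: pd.DataFrame
    pvalues: pd.DataFrame | None = None

    def edges(self) -> pd.DataFrame:
        """Long-format upper-triangle edge table."""
        taxa = list(self.correlations.index)
        rows = []
        for a in range(len(taxa)):
            for b in range(a + 1, len(taxa)):
                rows.append(
                    {
                        "feature_a": taxa[a],
                        "feature_b": taxa[b],
                        "r": float(self.correlations.iloc[a, b]),
                        "p": float(self.pvalues.iloc[a, b]) if self.pvalues is not None else np.nan,
                        "method": "sparcc",
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        e = self.edges()
        return (
            f"SparCC basis correlations: {len(self.correlations)} taxa, "
            f"{len(e)} edges, max |r| = {e['r'].abs().max():.3f}"
        )


def clr_rmcorr_edges(
    micro: OmicsMatrix,
    host: OmicsMatrix,
    metadata: VisitMetadata,
    phenotypes: SubjectPhenotype | None = None,
    group: str = "all",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Taxon-host edges: CLR-transformed microbiome vs host features, rmcorr.

    Computed over the healthy visits of the requested group (IS, IR or
    all); BH adjustment within the returned table.
    """
    from .events import fdr_adjust

    micro.require_state("clr")
    healthy = metadata.healthy()
    if group != "all":
        if phenotypes is None:
            raise ValueError("phenotypes required for IS/IR grouping")
        subjects = set(phenotypes.group_subjects(group))
        healthy = healthy[healthy["subject_id"].isin(subjects)]
    cols = [
        s for s in healthy["sample_id"] if s in micro.sample_ids and s in host.sample_ids
    ]
    if healthy[healthy["sample_id"].isin(cols)]["subject_id"].nunique() < 2:
        raise ValueError(f"group {group!r} has <2 eligible subjects")
    subj = healthy.set_index("sample_id")["subject_id"].reindex(cols)
    records = []
    for taxon in micro.feature_ids:
        tv = micro.data.loc[taxon, cols].to_numpy(dtype=float)
        for feat in host.feature_ids:
            hv = host.data.loc[feat, cols].to_numpy(dtype=float)
            try:
                res = rmcorr(tv, hv, subj.to_numpy())
            except ValueError:
                continue
            records.append(
                {
                    "feature_a": taxon,
                    "feature_b": feat,
                    "r": res["r"],
                    "p": res["p"],
                    "ci_lo": res["ci"][0],
                    "ci_hi": res["ci"][1],
                    "n_obs": res["n_obs"],
                    "method": "clr+rmcorr",
                    "group": group,
                }
            )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = fdr_adjust(table["p"].clip(lower=np.finfo(float).tiny))
        table["significant"] = table["q"] < q_threshold
    return table


def differential_edges(
    table_is: pd.DataFrame, table_ir: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Edges significant in exactly one of the IS / IR tables.

    Both tables must cover the identical pair universe. Returns the
    labelled differential edges; per-node counts of significant partners
    are attached as the ``node_counts`` attribute.
    """
    key = ["feature_a", "feature_b"]
    a = table_is.set_index(key)
    b = table_ir.set_index(key)
    if set(a.index) != set(b.index):
        raise ValueError("mismatched pair universes between IS and IR tables")
    b = b.reindex(a.index)
    sig_is = a["q"] < q_threshold
    sig_ir = b["q"] < q_threshold
    out = a.loc[sig_is ^ sig_ir, ["r", "q"]].rename(columns={"r": "r_is", "q": "q_is"})
    out["r_ir"] = b.loc[out.index, "r"]
    out["q_ir"] = b.loc[out.index, "q"]
    out["label"] = np.where(sig_is.loc[out.index], "IS-unique", "IR-unique")
    out = out.reset_index()
    counts: dict[str, dict[str, int]] = {"IS": {}, "IR": {}}
    for tab, grp in ((a[sig_is], "IS"), (b[sig_ir], "IR")):
        for fa, fb in tab.index:
            counts[grp][fa] = counts[grp].get(fa, 0) + 1
            counts[grp][fb] = counts[grp].get(fb, 0) + 1
    out.attrs["node_counts"] = counts
    return out


def group_interaction_test(x, y, subjects, groups) -> dict:
    """Group-by-x interaction in a varying-intercept model of y.

    Tests whether the within-subject slope of y on x differs between the
    IS and IR groups: OLS of y on subject indicators, x, and
    x * 1[group = IR]; returns the interaction coefficient's p-value.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"x": x, "y": y, "s": subjects, "g": groups}).dropna()
    dummies = pd.get_dummies(df["s"], drop_first=False, dtype=float)
    gx = df["x"].to_numpy() * (df["g"].to_numpy() == "IR")
    X = np.column_stack([dummies.to_numpy(), df["x"].to_numpy(), gx])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(df["y"].to_numpy(dtype=float), X).fit()
    return {"coef_interaction": float(fit.params[-1]), "p": float(fit.pvalues[-1])}
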