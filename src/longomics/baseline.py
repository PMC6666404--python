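"""Healthy-baseline variation: dispersion, variance decomposition,
individual embedding and monotone time associations.

Healthy visits are sampled repeatedly per subject, so each feature's
cohort variation splits into a between-subject part (personal setpoints)
and a within-subject part. The intra-class correlation (ICC) — the
fraction of total variance carried by subject random intercepts in a
linear mixed model with Days, A1C, SSPG and FPG as fixed covariates —
quantifies how individual a feature is. Features with the highest ICC
drive a non-metric MDS embedding of healthy visits (Manhattan
distances) in which subjects form personal clusters; an individuality
score summarises the average between-subject distance of personal
median profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import OmicsMatrix, SubjectPhenotype, VisitMetadata
from .events import fdr_adjust
from .networks import rmcorr


def iqr_type8(values) -> float:
    """Interquartile range with the median-unbiased (type-8) quantile estimator."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need >=3 observations for a dispersion estimate")
    q1, q3 = np.quantile(v, [0.25, 0.75], method="median_unbiased")
    return float(q3 - q1)


@dataclass
class DispersionResult:
    cohort_iqr: pd.Series  # per feature
    personal_iqrs: pd.DataFrame | None  # feature x subject
    flagged: list = field(default_factory=list)


def dispersion(
    matrix: OmicsMatrix, metadata: VisitMetadata, scope: str = "cohort"
) -> DispersionResult:
    """IQR of standardized healthy-visit values, cohort-wide or per subject.

    Values are standardized (mean 0, sd 1 over the cohort's healthy
    visits) before the IQR; per-subject IQRs require at least three
    healthy visits for that subject.
    """
    healthy = metadata.healthy()
    cols = [s for s in healthy["sample_id"] if s in matrix.sample_ids]
    if len(cols) < 3:
        raise ValueError("need >=3 healthy samples")
    vals = matrix.data[cols]
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flagged = list(matrix.feature_ids[~(sd > 0)])
    z = vals.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    z.loc[flagged] = 0.0
    cohort = z.apply(lambda row: iqr_type8(row.dropna()), axis=1)
    cohort.loc[flagged] = 0.0
    personal = None
    if scope == "per-subject":
        subj_of = healthy.set_index("sample_id")["subject_id"]
        per = {}
        for subj, grp in subj_of.groupby(subj_of):
            ids = [s for s in grp.index if s in z.columns]
            if len(ids) < 3:
                continue
            per[subj] = z[ids].apply(lambda row: iqr_type8(row.dropna()), axis=1)
        personal = pd.DataFrame(per)
    elif scope != "cohort":
        raise ValueError("scope must be 'cohort' or 'per-subject'")
    return DispersionResult(cohort_iqr=cohort, personal_iqrs=personal, flagged=flagged)


FIXED_COVARIATES = ("days", "a1c", "sspg", "fpg")


@dataclass
class VarianceDecomposition:
    """Per-feature random-intercept variance decomposition of healthy visits.

    Fits, per feature, a linear mixed model on the standardized values
    of healthy visits — fixed covariates Days, A1C, SSPG, FPG, a random
    intercept per subject, maximum-likelihood (not REML) estimation —
    and reports the ICC (random-intercept variance fraction of the unit
    total), sequential fixed-covariate fractions and the residual.
    Subjects missing SSPG are excluded from the fit.
    """

    matrix: OmicsMatrix
    metadata: VisitMetadata
    phenotypes: SubjectPhenotype

    def _design(self) -> pd.DataFrame:
        healthy = self.metadata.healthy()[["sample_id", "subject_id", "day"]]
        ph = self.phenotypes.table.set_index("subject_id")
        df = healthy.join(ph[["a1c", "sspg", "fpg"]], on="subject_id")
        df = df.rename(columns={"day": "days"})
        df = df.dropna(subset=["a1c", "sspg", "fpg"])
        return df

    def fit(self) -> "VarianceDecompositionResults":
        import statsmodels.api as sm

        design = self._design()
        records, flagged = [], []
        X_fixed = design[list(FIXED_COVARIATES)].to_numpy(dtype=float)
        groups = design["subject_id"].to_numpy()
        exog = np.column_stack([np.ones(len(design)), X_fixed])
        for feat in self.matrix.feature_ids:
            y = self.matrix.data.loc[feat].reindex(design["sample_id"]).to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 4 or pd.unique(groups[ok]).size < 2:
                flagged.append((feat, "insufficient healthy data"))
                continue
            ys = y[ok]
            sd = ys.std(ddof=0)
            if sd == 0:
                flagged.append((feat, "constant feature"))
                continue
            ys = (ys - ys.mean()) / sd  # total variation standardized to 1
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = sm.MixedLM(ys, exog[ok], groups=groups[ok])
                    res = md.fit(reml=False, method="lbfgs")
                cov_re = float(np.asarray(res.cov_re)[0, 0])
                scale = float(res.scale)
                fe_var = float(np.var(exog[ok] @ res.fe_params))
            except Exception:
                # boundary fits (variance component ~ 0) can leave a singular
                # Hessian; fall back to the one-way ANOVA moment estimator on
                # covariate-adjusted residuals
                try:
                    cov_re, scale, fe_var = self._anova_components(ys, exog[ok], groups[ok])
                except Exception:
                    flagged.append((feat, "singular fit"))
                    continue
            # response variance is standardized to 1: split the non-fixed
            # share by the between/within ratio (robust when the residual
            # variance degenerates to ~0 and cov_re's absolute value is
            # numerically arbitrary)
            fe_var = min(max(fe_var, 0.0), 1.0 - 1e-12)
            ratio = cov_re / (cov_re + scale) if cov_re + scale > 0 else 0.0
            icc = ratio * (1.0 - fe_var)
            resid = (1.0 - ratio) * (1.0 - fe_var)
            fracs = self._sequential_fractions(ys, exog[ok][:, 1:], fe_var)
            rec = {"feature": feat, "icc": icc, "residual": resid}
            rec.update({f"frac_{c}": fracs[i] for i, c in enumerate(FIXED_COVARIATES)})
            records.append(rec)
        return VarianceDecompositionResults(
            table=pd.DataFrame.from_records(records), flagged=flagged
        )

    @staticmethod
    def _anova_components(y, exog, groups):
        """ICC(1) moment estimator on OLS residuals (unbalanced-corrected)."""
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
        fitted = exog @ beta
        fe_var = float(np.var(fitted))
        r = y - fitted
        df = pd.DataFrame({"r": r, "g": groups})
        means = df.groupby("g")["r"].mean()
        sizes = df.groupby("g")["r"].size()
        k = len(means)
        n = len(df)
        ssb = float((sizes * (means - r.mean()) ** 2).sum())
        ssw = float(((df["r"] - means.reindex(df["g"]).to_numpy()) ** 2).sum())
        msb = ssb / (k - 1)
        msw = ssw / (n - k)
        n0 = (n - (sizes**2).sum() / n) / (k - 1)
        var_b = max((msb - msw) / n0, 0.0)
        return var_b, msw, fe_var

    @staticmethod
    def _sequential_fractions(y, X, fixed_total) -> np.ndarray:
        """Type-I (sequential) attribution of the fixed-effect variance.

        Incremental R^2 of OLS fits adding covariates in formula order,
        rescaled so the fractions sum to the mixed model's fixed-effect
        share (keeping icc + fixed + residual = 1 exactly).
        """
        n, k = X.shape
        inc = np.zeros(k)
        prev = 0.0
        ones = np.ones((n, 1))
        for j in range(k):
            Z = np.column_stack([ones, X[:, : j + 1]])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            r2 = 1.0 - np.sum((y - Z @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
            inc[j] = max(r2 - prev, 0.0)
            prev = max(r2, prev)
        total = inc.sum()
        if total <= 0 or fixed_total <= 0:
            return np.zeros(k)
        return inc / total * fixed_total


@dataclass
class VarianceDecompositionResults:
    table: pd.DataFrame
    flagged: list = field(default_factory=list)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Healthy-baseline variance decomposition (random subject intercepts, ML)",
            f"  features fitted: {len(t)}   flagged: {len(self.flagged)}",
        ]
        if len(t):
            lines.append(f"  median ICC: {t['icc'].median():.3f}")
            cols = ["feature", "icc"] + [f"frac_{c}" for c in FIXED_COVARIATES] + ["residual"]
            lines.append(
                t.sort_values("icc", ascending=False).head(10)[cols].to_string(
                    index=False, float_format=lambda v: f"{v:.3f}"
                )
            )
        return "\n".join(lines)

    def select_top_individual(self, n: int) -> list:
        """Top-n features by ICC, ties broken lexicographically by feature ID."""
        t = self.table
        if n > len(t):
            raise ValueError(f"requested {n} features but only {len(t)} available")
        ordered = t.sort_values(
            ["icc", "feature"], ascending=[False, True], kind="mergesort"
        )
        return ordered["feature"].head(n).tolist()


def select_top_individual(components: VarianceDecompositionResults | pd.DataFrame, n: int) -> list:
    if isinstance(components, pd.DataFrame):
        components = VarianceDecompositionResults(table=components)
    return components.select_top_individual(n)


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # sample x (dim1, dim2)
    stress: float
    features: list


def mds_embed(
    matrix: OmicsMatrix,
    metadata: VisitMetadata,
    features: list | None = None,
    seed: int = 0,
) -> EmbeddingResult:
    """Non-metric 2-D MDS of healthy visits on Manhattan distances."""
    from sklearn.manifold import MDS

    healthy = metadata.healthy()
    cols = [s for s in healthy["sample_id"] if s in matrix.sample_ids]
    if len(cols) < 3:
        raise ValueError("need >=3 healthy samples to embed")
    data = matrix.data[cols]
    if features is not None:
        data = data.loc[features]
    X = data.to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="cityblock"))
    if not np.any(D > 0):
        raise ValueError("degenerate (all-zero) distance matrix")
    mds = MDS(
        n_components=2,
        metric_mds=False,
        dissimilarity="precomputed",
        random_state=seed,
        n_init=4,
        normalized_stress="auto",
    )
    coords = mds.fit_transform(D)
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=cols, columns=["dim1", "dim2"]),
        stress=float(mds.stress_),
        features=list(data.index),
    )


def individuality_score(
    matrix: OmicsMatrix, metadata: VisitMetadata, features: list | None = None
) -> float:
    """Average between-subject Manhattan distance of personal median profiles.

    Per-subject medians over healthy visits are taken per feature; the
    score is the mean over all subject pairs of the Manhattan distance
    between median profiles, divided by the number of features. Higher
    scores mean more personally distinct profiles.
    """
    healthy = metadata.healthy()
    cols = [s for s in healthy["sample_id"] if s in matrix.sample_ids]
    data = matrix.data[cols]
    if features is not None:
        data = data.loc[features]
    subj_of = healthy.set_index("sample_id")["subject_id"]
    medians = data.T.groupby(subj_of.reindex(cols)).median()
    if len(medians) < 2:
        raise ValueError("need >=2 subjects with healthy visits")
    dists = pdist(medians.to_numpy(dtype=float), metric="cityblock")
    return float(dists.mean() / data.shape[0])


def time_association(matrix: OmicsMatrix, metadata: VisitMetadata) -> pd.DataFrame:
    """Repeated-measures correlation of healthy-visit changes with elapsed days.

    Per subject, each healthy visit after the first contributes
    (value - value_first, day - day_first); subjects need at least three
    healthy visits. The per-feature repeated-measures correlation of
    delta-value with delta-days is BH-adjusted across features.
    """
    healthy = metadata.healthy().sort_values("day")
    eligible = healthy.groupby("subject_id").filter(lambda g: len(g) >= 3)
    if eligible["subject_id"].nunique() < 2:
        raise ValueError("need >=2 subjects with >=3 healthy visits")
    records = []
    for feat in matrix.feature_ids:
        vals = matrix.data.loc[feat]
        dx, dy, subj = [], [], []
        for s, grp in eligible.groupby("subject_id"):
            v = vals.reindex(grp["sample_id"]).to_numpy(dtype=float)
            d = grp["day"].to_numpy(dtype=float)
            ok = np.isfinite(v)
            if ok.sum() < 3:
                continue
            v, d = v[ok], d[ok]
            dy.extend(v[1:] - v[0])
            dx.extend(d[1:] - d[0])
            subj.extend([s] * (len(v) - 1))
        try:
            r = rmcorr(dx, dy, subj)
        except ValueError:
            continue
        records.append(
            {
                "feature": feat,
                "r_rm": r["r"],
                "df": r["df"],
                "p": r["p"],
                "ci_lo": r["ci"][0],
                "ci_hi": r["ci"][1],
            }
        )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = fdr_adjust(table["p"].clip(lower=np.finfo(float).tiny))
    return table
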