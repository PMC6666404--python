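"""Pre-processing transforms for multi-omic matrices.

Each assay type gets the transform that makes its values approximately
Gaussian and comparable across samples: log2(n+1) for transcript counts,
natural log for MS intensities, arcsin(sqrt(p)) for relative abundances,
centred log-ratio for compositional analyses, median-of-ratios size
factors for sequencing depth, QC-anchored LOESS for mass-spec signal
drift, and k-nearest-neighbour imputation for missing intensities.

All functions take and return :class:`~longomics.containers.OmicsMatrix`
(recording the applied transform in the matrix history) unless noted;
:func:`clr_transform` also accepts bare arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import OmicsMatrix, StateError


def log_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Log-transform raw values.

    Transcript counts use log2(n + 1); intensity-valued omes use the
    natural log (which requires strictly positive values).
    """
    matrix.require_state(
        "raw", "size_factor_normalized", "imputed", "filtered", "drift_corrected"
    )
    if "log" in matrix.history:
        raise StateError("matrix already log-transformed")
    vals = matrix.values
    if matrix.ome == "transcriptome":
        if np.nanmin(vals) < 0:
            raise ValueError("negative counts")
        out = np.log2(vals + 1.0)
    else:
        if np.nanmin(vals) <= 0:
            raise ValueError("non-positive intensities under plain log")
        out = np.log(vals)
    return matrix.with_values(out, "log")


def arcsine_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Variance-stabilising arcsin(sqrt(p)) for relative abundances in [0, 1]."""
    matrix.require_state("raw", "imputed", "filtered")
    vals = matrix.values
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("relative abundances must lie in [0, 1]")
    return matrix.with_values(np.arcsin(np.sqrt(vals)), "arcsine")


def size_factors(matrix: OmicsMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The geometric mean of each feature is taken across samples (features
    containing any zero or missing value are excluded); each sample's
    factor is the median over features of value / geometric mean.
    """
    vals = matrix.values
    ok = np.all(np.isfinite(vals) & (vals > 0), axis=1)
    if not ok.any():
        raise ValueError("no feature with all-positive values; size factors undefined")
    sub = vals[ok]
    log_gmean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_gmean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize_by_size_factors(matrix: OmicsMatrix, factors: pd.Series | None = None) -> OmicsMatrix:
    if factors is None:
        factors = size_factors(matrix)
    f = factors.reindex(matrix.sample_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and defined for all samples")
    return matrix.with_values(matrix.values / f[None, :], "size_factor_normalized")


# -- presence / expression filters ---------------------------------------------

PRESENCE_RULES = ("metabolite_presence", "taxon_prevalence", "gene_abundance", "low_expression")


def presence_filter(
    matrix: OmicsMatrix,
    rule: str,
    metadata=None,
    *,
    min_fraction: float | None = None,
    abundance_threshold: float = 0.001,
    log_count_threshold: float = 5.0,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Apply one of the published presence/prevalence filters.

    ``metabolite_presence``
        keep features detected (non-missing, non-zero) in more than a
        third of samples.
    ``taxon_prevalence``
        keep taxa with abundance > 0 in more than half of samples.
    ``gene_abundance``
        keep microbial genes with relative abundance > 0.1% in more than
        half of samples.
    ``low_expression``
        drop genes whose log2 normalised count is below 5 in more than
        half of the subjects (per-subject mean when *metadata* is given,
        else per sample).

    Returns the filtered matrix and a report of removed features.
    """
    vals = matrix.values
    n = matrix.n_samples
    if rule == "metabolite_presence":
        frac = min_fraction if min_fraction is not None else 1.0 / 3.0
        present = np.isfinite(vals) & (vals != 0)
        keep = present.sum(axis=1) > frac * n
    elif rule == "taxon_prevalence":
        frac = min_fraction if min_fraction is not None else 0.5
        keep = (np.nan_to_num(vals) > 0).sum(axis=1) > frac * n
    elif rule == "gene_abundance":
        frac = min_fraction if min_fraction is not None else 0.5
        keep = (np.nan_to_num(vals) > abundance_threshold).sum(axis=1) > frac * n
    elif rule == "low_expression":
        logv = vals if "log" in matrix.history else np.log2(vals + 1.0)
        if metadata is not None:
            meta = metadata.table.set_index("sample_id")
            subj = meta.loc[matrix.sample_ids, "subject_id"].to_numpy()
            df = pd.DataFrame(logv, columns=matrix.sample_ids)
            per_subject = df.T.groupby(subj).mean().T.to_numpy()
        else:
            per_subject = logv
        low = per_subject < log_count_threshold
        keep = low.sum(axis=1) <= 0.5 * low.shape[1]
    else:
        raise ValueError(f"unknown presence rule {rule!r}; expected one of {PRESENCE_RULES}")

    removed = pd.DataFrame(
        {"feature": matrix.feature_ids[~keep], "rule": rule}
    ).reset_index(drop=True)
    out = matrix.with_data(matrix.data.loc[keep], "filtered" if (~keep).any() else None)
    return out, removed


def knn_impute(matrix: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing values from the k nearest samples.

    Distances are Euclidean over co-observed features after per-feature
    standardisation; imputed values are mapped back to the original
    scale and observed entries are left untouched.
    """
    vals = matrix.values
    if not np.isnan(vals).any():
        return matrix
    if np.all(np.isnan(vals), axis=0).any():
        raise ValueError("a sample has all values missing; cannot impute")
    mu = np.nanmean(vals, axis=1)
    sd = np.nanstd(vals, axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (vals - mu[:, None]) / sd[:, None]
    imputer = KNNImputer(n_neighbors=min(k, matrix.n_samples - 1), weights="uniform")
    z_imp = imputer.fit_transform(z.T).T  # samples as rows for the imputer
    filled = z_imp * sd[:, None] + mu[:, None]
    out = np.where(np.isnan(vals), filled, vals)
    return matrix.with_values(out, "imputed")


def loess_drift_correct(
    matrix: OmicsMatrix,
    injection_order,
    qc_flags,
    span: float = 0.75,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Correct per-feature MS signal drift using QC injections.

    For each feature a LOESS curve is fitted to the QC signal as a
    function of injection order; every sample is divided by the curve
    value at its own order, normalised to the curve mean so the global
    scale is preserved. Orders outside the QC range are clamped to the
    boundary fit value and flagged in the returned report.
    """
    order = np.asarray(injection_order, dtype=float)
    qc = np.asarray(qc_flags, dtype=bool)
    if order.shape[0] != matrix.n_samples or qc.shape[0] != matrix.n_samples:
        raise ValueError("injection_order and qc_flags must match sample count")
    if qc.sum() < 5:
        raise ValueError("need at least 5 QC samples to fit a drift curve")
    qc_order = order[qc]
    extrapolated = (order < qc_order.min()) | (order > qc_order.max())
    vals = matrix.values
    out = np.empty_like(vals)
    for i in range(matrix.n_features):
        y = vals[i, qc]
        obs = np.isfinite(y)
        if obs.sum() < 5 or np.nanstd(y) == 0:
            out[i] = vals[i]  # flat or unusable QC signal: identity correction
            continue
        fit = lowess(y[obs], qc_order[obs], frac=span, it=1, return_sorted=True)
        curve = np.interp(order, fit[:, 0], fit[:, 1])
        mean = curve[~extrapolated].mean() if (~extrapolated).any() else curve.mean()
        if mean == 0 or np.any(curve <= 0):
            out[i] = vals[i]
            continue
        out[i] = vals[i] / (curve / mean)
    report = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "extrapolated": extrapolated}
    )
    return matrix.with_values(out, "drift_corrected"), report


def clr_transform(x, pseudocount: float | None = None):
    """Centred log-ratio transform of compositions.

    ``x`` may be an :class:`OmicsMatrix` (features x samples; each sample
    is one composition), a DataFrame/ndarray of the same orientation, or
    a single composition vector. The default pseudocount is half the
    smallest non-zero value. Each composition's CLR values sum to zero.
    """
    if isinstance(x, OmicsMatrix):
        x.require_state("raw", "filtered", "imputed")
        out = clr_transform(x.values, pseudocount)
        return x.with_values(out, "clr")
    arr = np.asarray(x, dtype=float)
    vec = arr.ndim == 1
    mat = arr[:, None] if vec else arr
    if np.nanmin(mat) < 0:
        raise ValueError("compositions must be non-negative")
    if pseudocount is None:
        nz = mat[mat > 0]
        if nz.size == 0:
            raise ValueError("all-zero composition")
        # zero replacement only when needed: half the smallest nonzero value
        pseudocount = 0.0 if np.nanmin(mat) > 0 else 0.5 * nz.min()
    shifted = mat + pseudocount
    if np.nanmin(shifted) <= 0:
        raise ValueError("zero values with pseudocount = 0")
    logx = np.log(shifted)
    clr = logx - logx.mean(axis=0, keepdims=True)
    out = clr[:, 0] if vec else clr
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def standardize(matrix: OmicsMatrix, on_constant: str = "drop"):
    """Scale each feature to mean 0, sd 1 (sample sd, ddof=1).

    Constant features cannot be standardised; they are dropped and
    reported (``on_constant='drop'``) or raise (``'raise'``).
    """
    vals = matrix.values
    mu = np.nanmean(vals, axis=1)
    sd = np.nanstd(vals, axis=1, ddof=1)
    const = ~(sd > 0)
    if const.any() and on_constant == "raise":
        raise ValueError(f"constant features: {list(matrix.feature_ids[const])}")
    z = (vals[~const] - mu[~const, None]) / sd[~const, None]
    df = pd.DataFrame(z, index=matrix.feature_ids[~const], columns=matrix.sample_ids)
    out = matrix.with_data(df, "standardized")
    dropped = pd.Index(matrix.feature_ids[const])
    return out, dropped
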