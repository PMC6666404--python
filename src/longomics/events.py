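"""Differential response to stress events against personal baselines.

Visits around each stress event (respiratory viral infection or
immunization) are grouped into five ordered categories: pre-event
healthy baselines (preH, healthy visits within 186 days before onset),
event-early (EE, event days 1-6), event-late (EL, days 7-14), recovery
(RE, days 15-40) and post-event healthy (postH, healthy visits within
186 days after the last event visit).

The central statistic is an area-under-the-curve style deviation score.
Under the null each observation of a feature is Gaussian around a
subject-specific mean, ``X ~ N(mu_i, sigma^2)``. Event samples are
corrected by subtracting the subject's own surrounding healthy-baseline
mean; the statistic sums the corrected category means,

    AUC = (m_EE + m_EL + m_RE) / std_w ,

where ``std_w`` tracks the sampling weight of every observation entering
the numerator (event samples and the baseline visits subtracted from
them) so that the statistic is standard normal under the null. Writing
the numerator as a linear combination of raw observations, an event
sample in category a carries weight 1/|G_a|; each of a subject-event's
n_b baseline visits carries weight -c/n_b with c the summed event-sample
weights of that subject-event. Subject means then cancel exactly and

    Var(numerator) = sigma^2 * sum_units ( sum_s w_s^2 + c^2 / n_b ).

sigma^2 is estimated by pooling within-subject variance of the baseline
visits. Two-sided p-values come from N(0, 1) and are Benjamini-Hochberg
adjusted across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, VisitMetadata

EVENT_CATEGORIES = ("preH", "EE", "EL", "RE", "postH")
EVENT_STAGES = ("EE", "EL", "RE")

#: day windows relative to event onset (onset = event day 1), inclusive
EE_WINDOW = (1, 6)
EL_WINDOW = (7, 14)
RE_WINDOW = (15, 40)
HEALTHY_WINDOW_DAYS = 186


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _stage_of(event_day: float) -> str | None:
    if EE_WINDOW[0] <= event_day <= EE_WINDOW[1]:
        return "EE"
    if EL_WINDOW[0] <= event_day <= EL_WINDOW[1]:
        return "EL"
    if RE_WINDOW[0] <= event_day <= RE_WINDOW[1]:
        return "RE"
    return None


def categorize_visits(metadata: VisitMetadata, event_id) -> pd.DataFrame:
    """Label one event's visits with the five event categories.

    Returns a table (sample_id, subject_id, event_id, category, day,
    event_day); visits outside every window are omitted. Healthy visits
    are labelled per event, so a visit between two events may appear as
    postH for the earlier one and preH for the later one.
    """
    t = metadata.biological()
    ev = t[t.get("event_id").astype("object") == event_id] if "event_id" in t.columns else t.iloc[0:0]
    if len(ev) == 0:
        raise ValueError(f"event {event_id!r} has no visits")
    subject = ev["subject_id"].iloc[0]
    onset = int(ev["day"].iloc[0]) - int(ev["event_day"].iloc[0]) + 1
    rows = []
    for _, r in ev.iterrows():
        stage = _stage_of(r["event_day"])
        if stage is not None:
            rows.append((r["sample_id"], subject, event_id, stage, r["day"], r["event_day"]))
    if not all(r[3] in EVENT_STAGES for r in rows) or not rows:
        raise ValueError(f"event {event_id!r} has no visits in the EE/EL/RE windows")
    last_event_day = int(ev["day"].max())
    healthy = t[(t["subject_id"] == subject) & (t["visit_class"] == "healthy")]
    for _, r in healthy.iterrows():
        d = int(r["day"])
        if onset - HEALTHY_WINDOW_DAYS <= d < onset:
            rows.append((r["sample_id"], subject, event_id, "preH", d, np.nan))
        elif last_event_day < d <= last_event_day + HEALTHY_WINDOW_DAYS:
            rows.append((r["sample_id"], subject, event_id, "postH", d, np.nan))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "event_id", "category", "day", "event_day"]
    )


def categorize_all_events(metadata: VisitMetadata, event_type: str | None = None) -> pd.DataFrame:
    """Concatenate per-event category labels for all events of one class."""
    t = metadata.biological()
    if "event_id" not in t.columns:
        raise ValueError("metadata has no event_id column")
    ev = t[t["event_id"].notna()]
    if event_type is not None:
        ev = ev[ev["visit_class"] == event_type]
    frames = []
    for eid in pd.unique(ev["event_id"]):
        try:
            frames.append(categorize_visits(metadata, eid))
        except ValueError:
            continue  # events without EE/EL/RE visits are skipped
    if not frames:
        raise ValueError("no events with usable visits")
    return pd.concat(frames, ignore_index=True)


def baseline_correct(values: pd.Series, categorized: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject-event's healthy-baseline mean from its event samples.

    ``values`` maps sample_id to the feature's value. Returns a table of
    corrected event samples (columns: unit, subject_id, event_id,
    category, x_corrected, n_baseline) plus the baseline observations
    themselves (category preH/postH, x_baseline) for variance pooling.
    Subject-events with no preH/postH visit are dropped and recorded via
    the ``dropped_units`` attribute on the returned frame.
    """
    rows = []
    base_rows = []
    dropped = []
    for (subj, eid), grp in categorized.groupby(["subject_id", "event_id"], sort=False):
        base = grp[grp["category"].isin(["preH", "postH"])]
        evs = grp[grp["category"].isin(EVENT_STAGES)]
        bvals = values.reindex(base["sample_id"]).dropna()
        evals = values.reindex(evs["sample_id"]).dropna()
        if len(bvals) == 0 or len(evals) == 0:
            dropped.append((subj, eid))
            continue
        bmean = float(bvals.mean())
        unit = f"{subj}::{eid}"
        for sid, cat in zip(evs["sample_id"], evs["category"]):
            if sid in evals.index:
                rows.append((unit, subj, eid, cat, float(values[sid]) - bmean, len(bvals)))
        for v in bvals:
            base_rows.append((unit, subj, eid, float(v)))
    out = pd.DataFrame(
        rows, columns=["unit", "subject_id", "event_id", "category", "x_corrected", "n_baseline"]
    )
    out.attrs["baselines"] = pd.DataFrame(
        base_rows, columns=["unit", "subject_id", "event_id", "x_baseline"]
    )
    out.attrs["dropped_units"] = dropped
    return out


def pooled_baseline_variance(baseline_values, units) -> float:
    """Pooled within-unit variance of healthy-baseline observations.

    Residual sums of squares around each subject-event's baseline mean
    are summed and divided by the summed degrees of freedom; units with
    a single baseline visit contribute nothing.
    """
    b = np.asarray(baseline_values, dtype=float)
    u = np.asarray(units)
    ss = 0.0
    df = 0
    for unit in pd.unique(u):
        x = b[u == unit]
        if len(x) >= 2:
            ss += float(np.sum((x - x.mean()) ** 2))
            df += len(x) - 1
    if df == 0:
        raise ValueError("sigma is not estimable: need >=2 baseline visits in some unit")
    return ss / df


def auc_statistic(
    corrected,
    categories,
    units,
    n_baseline,
    sigma2: float,
):
    """Weight-tracked deviation statistic from baseline-corrected samples.

    Parameters
    ----------
    corrected, categories, units
        Parallel arrays over pooled event samples: corrected value,
        stage label (EE/EL/RE) and subject-event unit key.
    n_baseline
        Mapping (or parallel array) giving each sample's unit baseline
        size; only the per-unit value is used.
    sigma2
        Pooled within-subject baseline variance estimate.

    Returns a dict with the statistic, two-sided normal p, the summed
    corrected category means (numerator), the weighted standard
    deviation, and per-category corrected means and counts.
    """
    x = np.asarray(corrected, dtype=float)
    cat = np.asarray(categories)
    u = np.asarray(units)
    if x.size == 0:
        raise ValueError("no event samples")
    nb = np.asarray(n_baseline, dtype=float)
    if nb.shape != x.shape:
        raise ValueError("n_baseline must be given per sample")

    cat_means: dict[str, float] = {}
    cat_counts: dict[str, int] = {}
    w = np.zeros_like(x)
    for a in EVENT_STAGES:
        mask = cat == a
        if mask.any():
            cat_means[a] = float(x[mask].mean())
            cat_counts[a] = int(mask.sum())
            w[mask] = 1.0 / mask.sum()
        else:
            cat_means[a] = np.nan
            cat_counts[a] = 0
    numerator = float(np.sum(w * x))

    var_units = 0.0
    for unit in pd.unique(u):
        mask = u == unit
        c = float(w[mask].sum())
        n_b = float(nb[mask][0])
        var_units += float(np.sum(w[mask] ** 2)) + c * c / n_b
    if sigma2 <= 0:
        raise ValueError("sigma^2 must be positive")
    std_w = float(np.sqrt(sigma2 * var_units))
    statistic = numerator / std_w
    p = float(2.0 * stats.norm.sf(abs(statistic)))
    return {
        "statistic": statistic,
        "p": max(p, np.finfo(float).tiny),
        "numerator": numerator,
        "std_w": std_w,
        "sigma2": sigma2,
        "var_weight_sum": var_units,
        "cat_means": cat_means,
        "cat_counts": cat_counts,
    }


@dataclass
class AUCDeviationTest:
    """Per-feature deviation-from-personal-baseline test over stress events.

    Parameters
    ----------
    matrix
        Pre-processed feature x sample matrix.
    metadata
        Visit metadata with event annotations.
    event_type
        ``"infection"``, ``"immunization"`` or None (pool all events).
    subjects
        Optional subject subset (e.g. the insulin-sensitive group).
    """

    matrix: OmicsMatrix
    metadata: VisitMetadata
    event_type: str | None = None
    subjects: list | None = None

    def _categorized(self) -> pd.DataFrame:
        cat = categorize_all_events(self.metadata, self.event_type)
        if self.subjects is not None:
            cat = cat[cat["subject_id"].isin(self.subjects)]
        if len(cat) == 0:
            raise ValueError("no categorised samples for the requested events/subjects")
        return cat

    def fit(self) -> "AUCTestResults":
        cat = self._categorized()
        records = []
        flagged = []
        for feat in self.matrix.feature_ids:
            values = self.matrix.data.loc[feat]
            corr = baseline_correct(values, cat)
            if len(corr) == 0:
                flagged.append((feat, "no testable samples"))
                continue
            bases = corr.attrs["baselines"]
            try:
                sigma2 = pooled_baseline_variance(bases["x_baseline"], bases["unit"])
            except ValueError:
                flagged.append((feat, "sigma not estimable"))
                continue
            if sigma2 == 0:
                flagged.append((feat, "constant baselines"))
                continue
            nb = corr["n_baseline"].to_numpy(dtype=float)
            res = auc_statistic(
                corr["x_corrected"], corr["category"], corr["unit"], nb, sigma2
            )
            records.append(
                {
                    "feature": feat,
                    "statistic": res["statistic"],
                    "p": res["p"],
                    "m_EE": res["cat_means"]["EE"],
                    "m_EL": res["cat_means"]["EL"],
                    "m_RE": res["cat_means"]["RE"],
                    "n_EE": res["cat_counts"]["EE"],
                    "n_EL": res["cat_counts"]["EL"],
                    "n_RE": res["cat_counts"]["RE"],
                    "sigma_hat": float(np.sqrt(sigma2)),
                    "std_w": res["std_w"],
                }
            )
        table = pd.DataFrame.from_records(records)
        if len(table):
            table["q"] = fdr_adjust(table["p"])
        else:
            table["q"] = pd.Series(dtype=float)
        return AUCTestResults(table=table, flagged=flagged, event_type=self.event_type)


@dataclass
class AUCTestResults:
    """Results table of the deviation test, one row per testable feature."""

    table: pd.DataFrame
    flagged: list = field(default_factory=list)
    event_type: str | None = None

    def significant(self, q_threshold: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def summary(self, q_threshold: float = 0.1) -> str:
        n_sig = int((self.table["q"] < q_threshold).sum()) if len(self.table) else 0
        lines = [
            "Personal-baseline deviation test (AUC statistic)",
            f"  events:            {self.event_type or 'all'}",
            f"  features tested:   {len(self.table)}",
            f"  flagged/untested:  {len(self.flagged)}",
            f"  significant q<{q_threshold:g}: {n_sig}",
        ]
        if len(self.table):
            top = self.table.reindex(
                self.table["statistic"].abs().sort_values(ascending=False).index
            ).head(10)
            lines.append(
                top[["feature", "statistic", "p", "q", "m_EE", "m_EL", "m_RE"]]
                .to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)


def stage_paired_test(
    values: pd.Series, categorized: pd.DataFrame, stage: str
) -> dict:
    """Paired t-test of one event stage against personal baselines.

    Pairs are (per-subject stage mean, per-subject baseline mean) over
    the pooled events; subjects contributing both sides form the pairs.
    """
    if stage not in EVENT_STAGES:
        raise ValueError(f"stage must be one of {EVENT_STAGES}")
    pairs = []
    for subj, grp in categorized.groupby("subject_id", sort=True):
        sv = values.reindex(grp.loc[grp["category"] == stage, "sample_id"]).dropna()
        bv = values.reindex(
            grp.loc[grp["category"].isin(["preH", "postH"]), "sample_id"]
        ).dropna()
        if len(sv) and len(bv):
            pairs.append((float(sv.mean()), float(bv.mean())))
    if len(pairs) < 2:
        raise ValueError("need >=2 subjects with both stage and baseline samples")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return {
        "stage": stage,
        "t": t,
        "df": n - 1,
        "p": p,
        "mean_diff": float(d.mean()),
        "n_pairs": n,
    }


def stage_paired_tests(
    matrix: OmicsMatrix, categorized: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Stage-wise paired t-test for every feature, BH-adjusted."""
    records = []
    for feat in matrix.feature_ids:
        try:
            r = stage_paired_test(matrix.data.loc[feat], categorized, stage)
        except ValueError:
            continue
        r["feature"] = feat
        records.append(r)
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = fdr_adjust(table["p"].clip(lower=np.finfo(float).tiny))
    return table


def lr_time_test(values: pd.Series, metadata_rows: pd.DataFrame) -> dict:
    """Linear-regression comparator: value ~ time + subject indicators.

    Ordinary least squares with the calendar day as a real covariate and
    subject ID as a categorical covariate; returns the t-test on the
    time coefficient. Used as a standard longitudinal comparator to the
    deviation statistic.
    """
    import statsmodels.api as sm

    df = metadata_rows[["sample_id", "subject_id", "day"]].copy()
    df["y"] = values.reindex(df["sample_id"]).to_numpy()
    df = df.dropna(subset=["y"])
    if df["subject_id"].nunique() < 2 or df["day"].nunique() < 3:
        raise ValueError("need >=2 subjects and >=3 distinct time points")
    dummies = pd.get_dummies(df["subject_id"], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(df)), df["day"].to_numpy(dtype=float), dummies.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(df["y"].to_numpy(dtype=float), X).fit()
    return {"coef_time": float(fit.params[1]), "p": float(fit.pvalues[1]), "n": int(len(df))}


# -- null-model simulation of the statistic ------------------------------------

def simulate_null_auc(
    n_reps: int,
    n_subjects: int = 20,
    n_baseline: int = 5,
    stage_counts: dict | None = None,
    sigma: float = 1.0,
    subject_sd: float = 1.0,
    effect: dict | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo replicates of the deviation statistic.

    Each replicate draws, for every subject, a mean ``mu_i ~ N(0,
    subject_sd^2)``, ``n_baseline`` healthy visits and the stage samples
    (default 2 EE + 1 EL + 1 RE) as ``N(mu_i + delta_stage, sigma^2)``;
    the statistic is computed exactly as in the per-feature test, with
    sigma pooled from the simulated baselines. With ``effect=None`` this
    is the null model and the returned statistics should be N(0, 1).
    """
    rng = np.random.default_rng(seed)
    stage_counts = stage_counts or {"EE": 2, "EL": 1, "RE": 1}
    deltas = {a: 0.0 for a in EVENT_STAGES}
    if effect:
        deltas.update(effect)
    cats = np.concatenate(
        [np.repeat(a, stage_counts.get(a, 0)) for a in EVENT_STAGES]
    )
    per_subj = len(cats)
    cats_all = np.tile(cats, n_subjects)
    units_all = np.repeat(np.arange(n_subjects), per_subj)
    nb_all = np.full(n_subjects * per_subj, float(n_baseline))
    shift = np.tile(np.array([deltas[a] for a in cats]), n_subjects)
    base_units = np.repeat(np.arange(n_subjects), n_baseline)

    out = np.empty(n_reps)
    for r in range(n_reps):
        mu = rng.normal(0.0, subject_sd, n_subjects)
        baselines = rng.normal(np.repeat(mu, n_baseline), sigma)
        events = rng.normal(np.repeat(mu, per_subj) + shift, sigma)
        bmeans = baselines.reshape(n_subjects, n_baseline).mean(axis=1)
        corrected = events - np.repeat(bmeans, per_subj)
        resid = baselines.reshape(n_subjects, n_baseline)
        sigma2 = float(
            np.sum((resid - resid.mean(axis=1, keepdims=True)) ** 2)
            / (n_subjects * (n_baseline - 1))
        )
        out[r] = auc_statistic(corrected, cats_all, units_all, nb_all, sigma2)["statistic"]
    return out


def predicted_shift_mean(
    effect: dict,
    n_subjects: int = 20,
    n_baseline: int = 5,
    stage_counts: dict | None = None,
    sigma: float = 1.0,
) -> float:
    """Closed-form expected value of the statistic under additive stage shifts.

    The numerator's expectation is the sum of the injected per-stage
    shifts; dividing by the design's weighted standard deviation (with
    the true sigma) gives the non-centrality used for power prediction.
    """
    stage_counts = stage_counts or {"EE": 2, "EL": 1, "RE": 1}
    num = sum(effect.get(a, 0.0) for a in EVENT_STAGES if stage_counts.get(a, 0) > 0)
    var = 0.0
    # per subject: sum_s w_s^2 + c^2 / n_baseline, identical across subjects
    c = 0.0
    wsq = 0.0
    for a in EVENT_STAGES:
        k = stage_counts.get(a, 0)
        if k == 0:
            continue
        w = 1.0 / (k * n_subjects)
        wsq += k * w * w
        c += k * w
    var = n_subjects * (wsq + c * c / n_baseline)
    return num / (sigma * np.sqrt(var))


def predicted_power(
    effect: dict,
    alpha: float = 0.05,
    **design,
) -> float:
    """Normal-shift power prediction for the two-sided deviation test."""
    ncp = predicted_shift_mean(effect, **design)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))
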