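"""Synthetic longitudinal multi-omic cohorts with known ground truth.

The generator emulates a deep-phenotyping study design: quarterly
healthy visits per subject, dense sampling around stress events (two
visits in days 1-6, one in days 7-14, visits at weeks 3 and 5), subject
random intercepts with a target intra-class correlation, additive
stage-wise responses in a subset of features, compositional microbiome
layers with declared basis correlations, mass-spec run-order drift
observable in interleaved QC injections, and an insulin-resistant
subgroup with attenuated responses.

Values are generated on a latent Gaussian scale and mapped to each
assay's raw scale so that the standard transform recovers the latent
value exactly: intensities are ``exp(latent)`` (natural log inverts),
transcript "counts" are ``2**latent - 1`` (log2(n+1) inverts). Null
features therefore satisfy the subject-intercept Gaussian null model
exactly on the analysis scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SubjectPhenotype, VisitMetadata

TRAJECTORY_CLASSES = ("up-early", "up-late", "down-early", "down-late")

#: stage-shift profile per trajectory class; active stages carry the full
#: effect size (piecewise-constant additive shifts per category)
_CLASS_PROFILE = {
    "up-early": {"EE": 1.0, "EL": 1.0, "RE": 0.0},
    "up-late": {"EE": 0.0, "EL": 1.0, "RE": 1.0},
    "down-early": {"EE": -1.0, "EL": -1.0, "RE": 0.0},
    "down-late": {"EE": 0.0, "EL": -1.0, "RE": -1.0},
}


@dataclass
class OmeSpec:
    """Per-ome generation parameters.

    ``noise_sd`` is the residual sd on the latent (analysis) scale,
    ``icc`` the target fraction of variance from subject intercepts,
    ``responder_fraction`` the share of features reacting to events with
    latent stage shifts of ``effect_size * noise_sd`` shaped by a random
    trajectory class. Compositional omes ignore ``baseline_mean`` and
    draw log-basis abundances instead.
    """

    n_features: int = 50
    noise_sd: float = 1.0
    icc: float = 0.5
    responder_fraction: float = 0.1
    effect_size: float = 1.0
    stage_effects: dict | None = None
    baseline_mean: float = 0.0
    baseline_mean_sd: float = 1.0
    compositional: bool = False
    depth: int = 20000
    basis_correlations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not (0 <= self.icc < 1):
            raise ValueError("icc must lie in [0, 1)")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect sizes must be finite")


def default_ome_specs() -> dict[str, OmeSpec]:
    return {
        "transcriptome": OmeSpec(n_features=120, icc=0.35, baseline_mean=8.0, noise_sd=1.0),
        "metabolome": OmeSpec(n_features=80, icc=0.55, baseline_mean=2.0),
        "proteome": OmeSpec(n_features=60, icc=0.55, baseline_mean=3.0),
        "cytokine": OmeSpec(n_features=30, icc=0.45, baseline_mean=1.0),
        "clinical": OmeSpec(n_features=20, icc=0.6, baseline_mean=2.0),
        "gut16S": OmeSpec(n_features=40, icc=0.6, compositional=True),
        "nasal16S": OmeSpec(n_features=40, icc=0.45, compositional=True),
    }


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic cohort."""

    n_subjects: int = 50
    n_healthy_visits: int = 6
    healthy_spacing_days: float = 91.0
    healthy_spacing_jitter: float = 10.0
    event_rate: float = 1.0
    event_visit_offsets: tuple = (2, 5, 10, 21, 35)
    ome_specs: dict = field(default_factory=default_ome_specs)
    ir_fraction: float = 0.3
    response_attenuation_ir: float = 0.5
    drift_coefficient: float = 0.0015
    qc_interval: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_healthy_visits < 1:
            raise ValueError("counts must be >= 1")
        if self.healthy_spacing_days - 3 * self.healthy_spacing_jitter <= 0:
            raise ValueError("spacing/jitter can produce non-positive visit gaps")
        if any(o < 1 for o in self.event_visit_offsets):
            raise ValueError("event visit offsets are days since onset (>= 1)")
        if not (0 <= self.ir_fraction <= 1):
            raise ValueError("ir_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    responders: dict  # ome -> {feature: trajectory class}
    stage_shifts: dict  # ome -> {feature: {EE/EL/RE: latent shift}}
    true_icc: dict  # ome -> {feature: icc}
    basis_correlations: dict  # ome -> [(taxon_a, taxon_b, rho)]
    drift_coefficient: float
    sspg: dict  # subject -> mg/dl
    ir_is: dict  # subject -> "IR"/"IS"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _correlated_log_basis(n_taxa, n_samples, basis_correlations, rng, mean_sd=1.0):
    """Draw unit-variance log-basis abundances with declared pair correlations."""
    cov = np.eye(n_taxa)
    for i, j, rho in basis_correlations:
        i, j = int(i), int(j)
        if not (-1.0 < rho < 1.0):
            raise ValueError("basis correlations must lie in (-1, 1)")
        if i == j or not (0 <= i < n_taxa and 0 <= j < n_taxa):
            raise ValueError("invalid taxon pair")
        cov[i, j] = cov[j, i] = rho
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 1e-10:
        raise ValueError("declared basis correlations are not jointly consistent (not PD)")
    mu = rng.normal(0.0, mean_sd, n_taxa)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_taxa, n_samples))
    return mu[:, None] + L @ z


def generate_compositional_ome(
    n_taxa: int,
    n_samples: int,
    basis_correlations=(),
    depth: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Multinomial counts from correlated log-normal basis abundances.

    Each sample's counts sum exactly to ``depth``. At least 4 taxa are
    required for downstream basis-correlation estimation.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa for basis-correlation estimability")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    logb = _correlated_log_basis(n_taxa, n_samples, list(basis_correlations), rng)
    basis = np.exp(logb)
    frac = basis / basis.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(depth, frac[:, s]) for s in range(n_samples)]
    )
    taxa = [f"taxon_{i:03d}" for i in range(n_taxa)]
    samples = [f"S{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(counts, index=taxa, columns=samples)


def inject_run_order_drift(matrix: OmicsMatrix, injection_order, drift_coefficient: float) -> OmicsMatrix:
    """Multiply every feature by exp(coef * order): smooth, monotone drift."""
    order = np.asarray(injection_order, dtype=float)
    if order.shape[0] != matrix.n_samples:
        raise ValueError("injection_order must cover all samples")
    if drift_coefficient == 0:
        return matrix
    factor = np.exp(drift_coefficient * order)
    return matrix.with_values(matrix.values * factor[None, :])


def _subject_visit_days(cfg: CohortConfig, rng) -> list[np.ndarray]:
    days = []
    for _ in range(cfg.n_subjects):
        gaps = rng.normal(cfg.healthy_spacing_days, cfg.healthy_spacing_jitter, cfg.n_healthy_visits - 1)
        if np.any(gaps <= 0):
            gaps = np.clip(gaps, 1.0, None)
        d = np.concatenate([[1.0], 1.0 + np.cumsum(gaps)]).round().astype(int)
        days.append(d)
    return days


def generate_cohort(config: CohortConfig):
    """Generate (omics matrices, visit metadata, phenotypes, ground truth).

    Returns a dict of :class:`OmicsMatrix` keyed by ome, a
    :class:`VisitMetadata`, a :class:`SubjectPhenotype` and a
    :class:`GroundTruth`. All randomness derives from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    subjects = [f"SUBJ{i:03d}" for i in range(cfg.n_subjects)]

    # -- phenotypes ------------------------------------------------------------
    n_ir = int(round(cfg.ir_fraction * cfg.n_subjects))
    ir_flags = np.zeros(cfg.n_subjects, dtype=bool)
    ir_flags[rng.choice(cfg.n_subjects, n_ir, replace=False)] = True
    sspg = np.where(ir_flags, rng.uniform(150, 250, cfg.n_subjects), rng.uniform(70, 145, cfg.n_subjects))
    pheno = pd.DataFrame(
        {
            "subject_id": subjects,
            "sspg": np.round(sspg, 1),
            "bmi": np.round(rng.normal(28, 4, cfg.n_subjects), 1),
            "age": rng.integers(30, 66, cfg.n_subjects),
            "sex": rng.choice(["F", "M"], cfg.n_subjects),
            "a1c": np.round(rng.normal(5.6, 0.4, cfg.n_subjects), 2),
            "fpg": np.round(rng.normal(95, 10, cfg.n_subjects), 1),
        }
    )
    phenotypes = SubjectPhenotype(pheno)

    # -- visit schedule --------------------------------------------------------
    healthy_days = _subject_visit_days(cfg, rng)
    meta_rows = []
    sample_counter = 0

    def new_sample():
        nonlocal sample_counter
        sid = f"SAMP{sample_counter:05d}"
        sample_counter += 1
        return sid

    event_counter = 0
    subject_event_stage = {}  # sample_id -> (subject_idx, stage)
    for si, subj in enumerate(subjects):
        for d in healthy_days[si]:
            meta_rows.append((new_sample(), subj, int(d), "healthy", None, None))
        n_events = rng.poisson(cfg.event_rate)
        span_hi = int(healthy_days[si].max())
        for _ in range(n_events):
            eid = f"EV{event_counter:04d}"
            event_counter += 1
            onset = int(rng.integers(30, max(span_hi - 45, 31)))
            etype = "infection" if rng.random() < 0.6 else "immunization"
            # dense early sampling: two visits in days 1-6, then days 7-14, weeks 3 & 5
            for off in cfg.event_visit_offsets:
                meta_rows.append((new_sample(), subj, onset + int(off) - 1, etype, eid, int(off)))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"]
    )
    meta["is_qc"] = False
    bio_samples = meta["sample_id"].tolist()
    n_bio = len(bio_samples)

    # per-sample stage labels for response injection
    stage = pd.Series(index=meta["sample_id"], dtype="object")
    ed = meta.set_index("sample_id")["event_day"]
    stage[(ed >= 1) & (ed <= 6)] = "EE"
    stage[(ed >= 7) & (ed <= 14)] = "EL"
    stage[(ed >= 15) & (ed <= 40)] = "RE"
    subj_of = meta.set_index("sample_id")["subject_id"]
    atten = pd.Series(
        np.where(ir_flags[[subjects.index(s) for s in subj_of]], cfg.response_attenuation_ir, 1.0),
        index=subj_of.index,
    )

    matrices: dict[str, OmicsMatrix] = {}
    gt_resp: dict[str, dict] = {}
    gt_shift: dict[str, dict] = {}
    gt_icc: dict[str, dict] = {}
    gt_basis: dict[str, list] = {}

    for ome, spec in cfg.ome_specs.items():
        feats = [f"{ome}_f{k:04d}" for k in range(spec.n_features)]
        n_resp = int(round(spec.responder_fraction * spec.n_features))
        resp_idx = rng.choice(spec.n_features, n_resp, replace=False)
        classes = rng.choice(TRAJECTORY_CLASSES, n_resp)
        responders = {feats[i]: str(c) for i, c in zip(resp_idx, classes)}
        shifts = {}
        for i, c in zip(resp_idx, classes):
            if spec.stage_effects is not None:
                prof = dict(spec.stage_effects)
            else:
                prof = {
                    a: v * spec.effect_size * spec.noise_sd
                    for a, v in _CLASS_PROFILE[str(c)].items()
                }
            shifts[feats[i]] = prof
        gt_resp[ome] = responders
        gt_shift[ome] = shifts
        gt_icc[ome] = {f: spec.icc for f in feats}

        subj_sd = spec.noise_sd * np.sqrt(spec.icc / (1 - spec.icc)) if spec.icc > 0 else 0.0

        if spec.compositional:
            # correlated pairs among the first taxa by default, none unless declared
            pairs = list(spec.basis_correlations)
            gt_basis[ome] = [(feats[int(i)], feats[int(j)], float(r)) for i, j, r in pairs]
            logb = _correlated_log_basis(spec.n_features, n_bio, pairs, rng)
            intercepts = rng.normal(0.0, subj_sd, (spec.n_features, cfg.n_subjects))
            sidx = np.array([subjects.index(s) for s in subj_of[bio_samples]])
            latent = logb * spec.noise_sd + intercepts[:, sidx]
            # stage responses on the log-basis scale
            for f, prof in shifts.items():
                fi = feats.index(f)
                for k, sid in enumerate(bio_samples):
                    st = stage.get(sid)
                    if isinstance(st, str):
                        latent[fi, k] += prof[st] * atten[sid]
            basis = np.exp(latent)
            frac = basis / basis.sum(axis=0, keepdims=True)
            counts = np.column_stack(
                [rng.multinomial(spec.depth, frac[:, s]) for s in range(n_bio)]
            )
            rel = counts / float(spec.depth)
            df = pd.DataFrame(rel, index=feats, columns=bio_samples)
            matrices[ome] = OmicsMatrix(ome, df)
            continue

        mu_f = rng.normal(spec.baseline_mean, spec.baseline_mean_sd, spec.n_features)
        intercepts = rng.normal(0.0, subj_sd, (spec.n_features, cfg.n_subjects))
        sidx = np.array([subjects.index(s) for s in subj_of[bio_samples]])
        latent = (
            mu_f[:, None]
            + intercepts[:, sidx]
            + rng.normal(0.0, spec.noise_sd, (spec.n_features, n_bio))
        )
        for f, prof in shifts.items():
            fi = feats.index(f)
            for k, sid in enumerate(bio_samples):
                st = stage.get(sid)
                if isinstance(st, str):
                    latent[fi, k] += prof[st] * atten[sid]

        cols = list(bio_samples)
        if ome == "metabolome":
            # interleave QC injections every qc_interval biological samples
            qc_profile = mu_f + rng.normal(0.0, 0.2, spec.n_features)
            order = []
            qc_cols = []
            qc_latent = []
            inj = 0
            inj_of = {}
            for k, sid in enumerate(bio_samples):
                if k % cfg.qc_interval == 0:
                    qsid = f"QC{len(qc_cols):04d}"
                    qc_cols.append(qsid)
                    qc_latent.append(qc_profile + rng.normal(0.0, 0.05, spec.n_features))
                    inj_of[qsid] = inj
                    inj += 1
                inj_of[sid] = inj
                inj += 1
            qsid = f"QC{len(qc_cols):04d}"
            qc_cols.append(qsid)
            qc_latent.append(qc_profile + rng.normal(0.0, 0.05, spec.n_features))
            inj_of[qsid] = inj
            all_cols = cols + qc_cols
            vals = np.exp(np.column_stack([latent, np.column_stack(qc_latent)]))
            orders = np.array([inj_of[c] for c in all_cols], dtype=float)
            df = pd.DataFrame(vals, index=feats, columns=all_cols)
            m = OmicsMatrix(ome, df)
            m = inject_run_order_drift(m, orders, cfg.drift_coefficient)
            matrices[ome] = m
            qc_meta = pd.DataFrame(
                {
                    "sample_id": qc_cols,
                    "subject_id": "QC",
                    "day": 0,
                    "visit_class": "other",
                    "event_id": pd.Series([None] * len(qc_cols), dtype=object),
                    "event_day": pd.Series([np.nan] * len(qc_cols), dtype=float),
                    "is_qc": True,
                }
            )
            meta["event_id"] = meta["event_id"].astype(object)
            meta["event_day"] = meta["event_day"].astype(float)
            meta = pd.concat([meta, qc_meta], ignore_index=True)
            meta["injection_order"] = meta["sample_id"].map(inj_of)
        elif ome == "transcriptome":
            vals = np.maximum(np.exp2(latent) - 1.0, 0.0)
            matrices[ome] = OmicsMatrix(ome, pd.DataFrame(vals, index=feats, columns=cols))
        else:
            vals = np.exp(latent)
            matrices[ome] = OmicsMatrix(ome, pd.DataFrame(vals, index=feats, columns=cols))

    # MCAR missingness on intensity omes (never on metabolome QCs)
    if cfg.missing_rate > 0:
        for ome in ("metabolome", "proteome", "cytokine"):
            if ome not in matrices:
                continue
            m = matrices[ome]
            vals = m.values
            mask = rng.random(vals.shape) < cfg.missing_rate
            is_qc_col = np.array([c.startswith("QC") for c in m.sample_ids])
            mask[:, is_qc_col] = False
            vals[mask] = np.nan
            matrices[ome] = m.with_values(vals)

    metadata = VisitMetadata(meta)
    truth = GroundTruth(
        responders=gt_resp,
        stage_shifts=gt_shift,
        true_icc=gt_icc,
        basis_correlations=gt_basis,
        drift_coefficient=cfg.drift_coefficient,
        sspg={s: float(v) for s, v in zip(subjects, sspg)},
        ir_is={s: ("IR" if f else "IS") for s, f in zip(subjects, ir_flags)},
    )
    return matrices, metadata, phenotypes, truth


def write_bundle(matrices, metadata, phenotypes, truth, outdir) -> None:
    """Write the standard bundle: one TSV per ome, metadata and phenotype TSVs,
    ground-truth JSON manifest."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ome, m in matrices.items():
        m.data.to_csv(out / f"{ome}.tsv", sep="\t")
    metadata.to_tsv(out / "metadata.tsv")
    phenotypes.to_tsv(out / "phenotypes.tsv")
    truth.to_json(out / "ground_truth.json")
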