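"""Core data containers for longitudinal multi-omics profiling.

The data model mirrors how deep-phenotyping cohorts are organised in
practice: one feature-by-sample value matrix per molecular assay ("ome"),
a visit-level metadata table linking samples to subjects, calendar days
and stress events, and a subject-level phenotype table carrying insulin
resistance and related clinical covariates.

All tables are pandas DataFrames underneath; the wrapper classes add
validation and, for :class:`OmicsMatrix`, an append-only record of the
transformations applied so that downstream analyses can assert they are
operating on correctly pre-processed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OME_LABELS = frozenset(
    {
        "transcriptome",
        "proteome",
        "metabolome",
        "cytokine",
        "clinical",
        "gut16S",
        "nasal16S",
        "microbial_gene",
    }
)

#: omes whose raw values are compositional (relative abundances in [0, 1])
COMPOSITIONAL_OMES = frozenset({"gut16S", "nasal16S", "microbial_gene"})

TRANSFORM_STATES = (
    "raw",
    "log",
    "arcsine",
    "clr",
    "standardized",
    "size_factor_normalized",
    "drift_corrected",
    "imputed",
    "filtered",
)

VISIT_CLASSES = frozenset({"healthy", "infection", "immunization", "antibiotics", "other"})

#: SSPG threshold (mg/dl) separating insulin-sensitive from insulin-resistant
SSPG_IR_THRESHOLD = 150.0


class StateError(ValueError):
    """A transform was applied to a matrix in an incompatible state."""


@dataclass
class OmicsMatrix:
    """One ome's feature-by-sample value matrix with transformation state.

    Parameters
    ----------
    ome
        Assay label, one of :data:`OME_LABELS`.
    data
        DataFrame with unique feature IDs as the index and unique sample
        IDs as columns. Values are counts, intensities or relative
        abundances depending on the ome.
    history
        Append-only list of transformation tags; the last entry is the
        current state. New matrices start as ``["raw"]``.
    """

    ome: str
    data: pd.DataFrame
    history: list[str] = field(default_factory=lambda: ["raw"])

    def __post_init__(self) -> None:
        if self.ome not in OME_LABELS:
            raise ValueError(f"unknown ome label {self.ome!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        for tag in self.history:
            if tag not in TRANSFORM_STATES:
                raise ValueError(f"unknown transformation tag {tag!r}")
        if self.state == "raw":
            vals = self.data.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and finite.min() < 0:
                raise ValueError("raw values must be non-negative")
            if self.ome in COMPOSITIONAL_OMES and finite.size and finite.max() <= 1.0:
                # relative abundances; counts (max > 1) are also accepted
                pass

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def state(self) -> str:
        return self.history[-1]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values, new_state: str | None = None) -> "OmicsMatrix":
        """Return a copy holding *values* and, optionally, an appended state tag."""
        df = pd.DataFrame(
            np.asarray(values, dtype=float), index=self.data.index, columns=self.data.columns
        )
        history = list(self.history)
        if new_state is not None:
            history.append(new_state)
        return OmicsMatrix(self.ome, df, history)

    def with_data(self, data: pd.DataFrame, new_state: str | None = None) -> "OmicsMatrix":
        history = list(self.history)
        if new_state is not None:
            history.append(new_state)
        return OmicsMatrix(self.ome, data, history)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"{self.ome} matrix is in state {self.state!r}; expected one of {allowed}"
            )


def load_matrix(path, ome: str, sep: str = "\t") -> OmicsMatrix:
    """Read a feature-by-sample delimited text matrix.

    The first row holds sample IDs, the first column feature IDs. Numeric
    parse failures are reported with their (feature, sample) coordinates.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    mask = (numeric.isna() & df.notna()).to_numpy()
    if mask.any():
        bad = [
            (str(df.index[i]), str(df.columns[j])) for i, j in zip(*np.nonzero(mask))
        ]
        raise ValueError(f"non-numeric entries at (feature, sample): {bad[:10]}")
    return OmicsMatrix(ome, numeric.astype(float))


def write_matrix(matrix: OmicsMatrix, path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep)


@dataclass
class VisitMetadata:
    """Per-sample visit annotations.

    Columns: ``sample_id``, ``subject_id``, ``day`` (integer days from the
    subject's study start), ``visit_class`` (healthy / infection /
    immunization / antibiotics / other), optional ``event_id`` and
    ``event_day`` (offset from event onset; onset is day 1), optional
    ``injection_order`` and ``is_qc`` for mass-spectrometry run order.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "day", "visit_class")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id rows in metadata")
        if (t["day"] < 0).any():
            raise ValueError("days must be non-negative")
        unknown = set(t["visit_class"]) - VISIT_CLASSES
        if unknown:
            raise ValueError(f"unknown visit classes: {unknown}")
        if "event_id" in t.columns and "event_day" in t.columns:
            has_event = t["event_id"].notna()
            if (has_event != t["event_day"].notna()).any():
                raise ValueError("event_day must be present iff event_id is present")
        if "is_qc" not in t.columns:
            self.table = t.assign(is_qc=False)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def biological(self) -> pd.DataFrame:
        """Rows for biological (non-QC) samples."""
        return self.table[~self.table["is_qc"].astype(bool)]

    def healthy(self) -> pd.DataFrame:
        bio = self.biological()
        return bio[bio["visit_class"] == "healthy"]

    def for_samples(self, sample_ids) -> "VisitMetadata":
        t = self.table[self.table["sample_id"].isin(list(sample_ids))]
        return VisitMetadata(t.reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path) -> "VisitMetadata":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SubjectPhenotype:
    """Per-subject phenotypes: SSPG, IR/IS label, BMI, age, sex, A1C, FPG.

    The IR/IS label is derived: insulin-resistant iff SSPG >= 150 mg/dl,
    insulin-sensitive below; subjects without an SSPG measurement carry a
    missing label.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "subject_id" not in t.columns:
            raise ValueError("phenotype table missing subject_id")
        if t["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id rows")
        if "sspg" in t.columns:
            derived = np.where(
                t["sspg"].isna(), None, np.where(t["sspg"] >= SSPG_IR_THRESHOLD, "IR", "IS")
            )
            if "ir_is" in t.columns:
                have = t["sspg"].notna()
                if not (t.loc[have, "ir_is"].to_numpy() == derived[have.to_numpy()]).all():
                    raise ValueError("ir_is labels inconsistent with SSPG threshold 150 mg/dl")
            else:
                self.table = t.assign(ir_is=derived)

    @property
    def subject_ids(self) -> pd.Index:
        return pd.Index(self.table["subject_id"])

    def group_subjects(self, group: str) -> list:
        """Subject IDs in group ``IS``, ``IR`` or ``all``."""
        if group == "all":
            return self.table["subject_id"].tolist()
        if group not in {"IS", "IR"}:
            raise ValueError(f"unknown group {group!r}")
        t = self.table
        return t.loc[t["ir_is"] == group, "subject_id"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "SubjectPhenotype":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
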