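import numpy as np
import pandas as pd
import pytest

import longomics as lo


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort with default omes and mild missingness."""
    cfg = lo.CohortConfig(n_subjects=20, seed=42, missing_rate=0.02)
    mats, meta, pheno, truth = lo.generate_cohort(cfg)
    return {"matrices": mats, "metadata": meta, "phenotypes": pheno, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def healthy_only_cohort():
    """100 subjects x 6 quarterly healthy visits, no events, for baseline stats."""
    rng = np.random.default_rng(3)
    n_s, n_v = 100, 6
    subjects = [f"S{i:03d}" for i in range(n_s)]
    rows = []
    k = 0
    for s in subjects:
        for v in range(n_v):
            rows.append((f"X{k:05d}", s, 1 + 91 * v, "healthy", None, np.nan))
            k += 1
    meta = lo.VisitMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"],
        )
    )
    pheno = lo.SubjectPhenotype(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "sspg": rng.uniform(80, 220, n_s),
                "bmi": rng.normal(28, 4, n_s),
                "age": rng.integers(30, 65, n_s),
                "sex": rng.choice(["F", "M"], n_s),
                "a1c": rng.normal(5.6, 0.4, n_s),
                "fpg": rng.normal(95, 10, n_s),
            }
        )
    )
    return meta, pheno, subjects


def make_matrix(values, ome="proteome", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return lo.OmicsMatrix(ome, pd.DataFrame(values, index=features, columns=samples))


@pytest.fixture
def matrix_factory():
    return make_matrix
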