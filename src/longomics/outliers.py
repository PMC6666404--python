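"""Personal outlier profiles against healthy baselines.

Each analyte is centred at the subject's own healthy-visit median and
scaled by the cohort-wide sd of the centred values; samples above an
analyte's 95th percentile of this z distribution are outlier calls.
Per-subject outlier composition across assays is the per-ome call count
normalised to the ome's analyte count and rescaled to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, VisitMetadata


def personal_zscores(
    matrix: OmicsMatrix,
    metadata: VisitMetadata,
    min_healthy_visits: int = 3,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Z-scores centred at each subject's healthy median.

    Only subjects with at least ``min_healthy_visits`` healthy visits are
    retained; analytes missing or zero in more than half the samples are
    dropped. The scale is the cohort sd (ddof=1) of the median-centred
    values per analyte.
    """
    bio = metadata.biological()
    healthy = bio[bio["visit_class"] == "healthy"]
    n_healthy = healthy.groupby("subject_id").size()
    subjects = n_healthy[n_healthy >= min_healthy_visits].index
    rows = bio[bio["subject_id"].isin(subjects)]
    cols = [s for s in rows["sample_id"] if s in matrix.sample_ids]
    if not cols:
        raise ValueError("no eligible samples")
    data = matrix.data[cols]
    bad = ((data.isna() | (data == 0)).sum(axis=1) > max_missing_fraction * len(cols))
    data = data.loc[~bad]
    subj_of = rows.set_index("sample_id")["subject_id"].reindex(cols)
    hcols = [s for s in healthy["sample_id"] if s in data.columns]
    med = data[hcols].T.groupby(subj_of.reindex(hcols)).median().T  # feature x subject
    centered = data.sub(med[subj_of.to_numpy()].set_axis(cols, axis=1), axis=0)
    scale = centered.std(axis=1, ddof=1)
    z = centered.div(scale.where(scale > 0, 1.0), axis=0)
    z = z.loc[scale > 0]
    return z


def call_outliers(z: pd.DataFrame, two_sided: bool = False, percentile: float = 95.0) -> pd.DataFrame:
    """Boolean calls: z above the analyte's own 95th-percentile threshold.

    With ``two_sided=True`` the threshold applies to \\|z\\| instead of the
    signed upper tail.
    """
    v = z.abs() if two_sided else z
    thr = v.quantile(percentile / 100.0, axis=1)
    return v.gt(thr, axis=0)


@dataclass
class OutlierProfile:
    proportions: pd.DataFrame  # subject x ome, percentages summing to 100
    counts: pd.DataFrame  # subject x ome raw call counts
    ome_sizes: dict

    def summary(self) -> str:
        return (
            "Per-subject outlier composition (% of outlier burden per assay)\n"
            + self.proportions.round(1).to_string()
        )


def ome_proportions(calls: dict[str, pd.DataFrame], metadata: VisitMetadata) -> OutlierProfile:
    """Per-subject outlier composition across assays.

    ``calls`` maps ome label to its boolean call matrix (analyte x
    sample). Counts per subject and ome are normalised by the ome's
    analyte count, then rescaled to sum to 100% across omes for each
    subject with any outlier.
    """
    subj_of = metadata.biological().set_index("sample_id")["subject_id"]
    counts = {}
    sizes = {}
    for ome, c in calls.items():
        sizes[ome] = c.shape[0]
        per_sample = c.sum(axis=0)
        counts[ome] = per_sample.groupby(subj_of.reindex(c.columns)).sum()
    count_df = pd.DataFrame(counts).fillna(0.0)
    normed = count_df / pd.Series(sizes)
    totals = normed.sum(axis=1)
    props = normed.div(totals.where(totals > 0, 1.0), axis=0) * 100.0
    props[totals == 0] = 0.0
    return OutlierProfile(proportions=props, counts=count_df, ome_sizes=sizes)
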