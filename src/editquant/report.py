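"""Cohort-level aggregation: per-sample statistics to group mean +/- SEM.

Deliberately stops at means and standard errors; group-comparison tests
(rank tests, ANOVA, survival) are off-the-shelf and outside this package.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import InputError

__all__ = ["summarize_cohort"]


def summarize_cohort(samples: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-sample statistics into mean +/- SEM per group.

    ``samples`` needs columns sample_id, assay, statistic, value (and
    optionally n). All rows must share one assay; SEM is the sample standard
    deviation (ddof=1) over sqrt(n_samples), NA for a single sample.
    """
    required = {"sample_id", "assay", "statistic", "value"}
    if samples.empty:
        raise InputError("no samples to summarize")
    if not required.issubset(samples.columns):
        raise InputError(f"summary input needs columns {sorted(required)}")
    if samples["assay"].nunique() > 1:
        raise InputError(
            f"refusing to pool mixed assays: {sorted(samples['assay'].unique())}"
        )
    rows = []
    for stat, grp in samples.groupby("statistic", sort=True):
        vals = grp["value"].astype(float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "assay": grp["assay"].iloc[0],
                "statistic": stat,
                "n_samples": n,
                "mean": float(vals.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)
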