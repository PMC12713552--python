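"""Packaged normative reference constants.

The normative study population (349 histologically normal biopsies, ages
4 weeks to 25 years, 18 age cohorts) is not publicly deposited, so its
published summary statistics ship with the package as reference CSVs:

``cohort_stats.csv``
    Pooled fiber-level minFeret statistics per (cohort, sex): fiber and
    biopsy counts, mean, SD, median (μm).
``sex_percentiles.csv``
    Per-biopsy percentile summaries per (cohort, sex): mean ± SD of each
    biopsy's 5/25/50/75/95th minFeret percentile, with the published
    male-vs-female p-value per level. The single 10-12-month male biopsy
    has no SD. Two printed male cells are internally non-monotone in the
    source table and are carried verbatim.
``cohort_size_filters.csv``
    Editable per-cohort minFeret plausibility range (μm) used by the
    morphometry size filter. The defaults are permissive placeholders
    (2-120 μm), not study-derived thresholds.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

PERCENTILE_LEVELS = (5, 25, 50, 75, 95)


def _data_path(name: str):
    return resources.files("myosize.data").joinpath(name)


@lru_cache(maxsize=None)
def load_cohort_stats() -> pd.DataFrame:
    """Pooled fiber statistics by cohort and sex (reference constants)."""
    with resources.as_file(_data_path("cohort_stats.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def load_sex_percentiles() -> pd.DataFrame:
    """Per-biopsy percentile summaries (mean ± SD) by cohort, sex, level."""
    with resources.as_file(_data_path("sex_percentiles.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=None)
def load_cohort_size_filters() -> pd.DataFrame:
    """Default per-cohort minFeret plausibility thresholds (editable)."""
    with resources.as_file(_data_path("cohort_size_filters.csv")) as p:
        return pd.read_csv(p)


def cohort_stats_row(cohort: str, sex: str) -> pd.Series:
    """Return the pooled-statistics row for one cohort/sex cell."""
    from .norms import canonical_cohort_id
    from .samples import normalize_sex

    cid = canonical_cohort_id(cohort)
    s = normalize_sex(sex)
    df = load_cohort_stats()
    row = df[(df["cohort"] == cid) & (df["sex"] == s)]
    if row.empty:
        raise KeyError(f"no reference statistics for cohort {cohort!r}, sex {sex!r}")
    return row.iloc[0]
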