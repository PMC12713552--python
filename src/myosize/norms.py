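"""Age-cohort assignment and normative fiber-size tables.

The study partitions ages between birth and the end of the 25th year into
18 cohorts: quarterly bins through the first year, yearly bins through age
9, then 10-12, 13-15, 16-18, 19-21 and 22-25 years. Normative summaries
are two-stage: each biopsy contributes its own minFeret percentiles
(5, 25, 50, 75, 95), and a (cohort, sex) cell reports the mean ± SD of
those per-biopsy percentiles, alongside pooled fiber-level statistics.
Sexes are compared per percentile level with a Welch two-sample test on
the per-biopsy percentile values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import PERCENTILE_LEVELS, load_cohort_stats, load_sex_percentiles
from .samples import BiopsySample, normalize_sex

#: (cohort id, low, high) in completed months, half-open [low, high)
COHORTS: tuple[tuple[str, float, float], ...] = (
    ("0-3 months", 0, 4),
    ("4-6 months", 4, 7),
    ("7-9 months", 7, 10),
    ("10-12 months", 10, 13),
    ("1 year", 13, 24),
    ("2 years", 24, 36),
    ("3 years", 36, 48),
    ("4 years", 48, 60),
    ("5 years", 60, 72),
    ("6 years", 72, 84),
    ("7 years", 84, 96),
    ("8 years", 96, 108),
    ("9 years", 108, 120),
    ("10-12 years", 120, 156),
    ("13-15 years", 156, 192),
    ("16-18 years", 192, 228),
    ("19-21 years", 228, 264),
    ("22-25 years", 264, 312),
)

COHORT_IDS: tuple[str, ...] = tuple(c[0] for c in COHORTS)

#: cohorts pooled across sexes in the under-2-years growth-curve export
POOLED_UNDER_2Y: tuple[str, ...] = COHORT_IDS[: COHORT_IDS.index("2 years") + 1]

_ALIASES = {
    "0-3 mo": "0-3 months",
    "4-6 mo": "4-6 months",
    "7-9 mo": "7-9 months",
    "10-12 mo": "10-12 months",
    "1 y": "1 year",
    "2 y": "2 years",
    "3 y": "3 years",
    "4 y": "4 years",
    "5 y": "5 years",
    "6 y": "6 years",
    "7 y": "7 years",
    "8 y": "8 years",
    "9 y": "9 years",
    "10-12 y": "10-12 years",
    "13-15 y": "13-15 years",
    "16-18 y": "16-18 years",
    "19-21 y": "19-21 years",
    "22-25 y": "22-25 years",
}


def canonical_cohort_id(cohort: str) -> str:
    """Normalize a cohort label to its canonical id; raise if unknown."""
    c = str(cohort).strip()
    c = _ALIASES.get(c, c)
    if c not in COHORT_IDS:
        raise KeyError(f"unknown age cohort {cohort!r}; expected one of {COHORT_IDS}")
    return c


def assign_cohort(age_months: float) -> str:
    """Map an age in completed months onto its age cohort.

    Ages are real-valued months in [0, 312). The first year is split into
    quarterly cohorts (12 months still counts as "10-12 months"); "1 year"
    covers months 13-23, yearly cohorts follow through age 9, and the
    remaining cohorts span 3-4 years each.
    """
    a = float(age_months)
    if not np.isfinite(a) or not 0 <= a < 312:
        raise ValueError(f"age {age_months} months outside the study range [0, 312)")
    for cid, lo, hi in COHORTS:
        if lo <= a < hi:
            return cid
    raise AssertionError("unreachable: cohorts cover [0, 312)")


def biopsy_percentiles(values: Sequence[float], levels: Sequence[float] = PERCENTILE_LEVELS) -> np.ndarray:
    """Percentiles of one biopsy's minFeret values (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute percentiles of an empty biopsy")
    return np.percentile(v, levels, method="linear")


@dataclass
class NormativeTable:
    """Two-stage normative summaries per (cohort, sex).

    Attributes
    ----------
    cells
        One row per (cohort, sex) with ``n_biopsies``, per-level
        ``p{level}_mean``/``p{level}_sd`` (SD is NaN when a single biopsy
        is available), and pooled fiber-level ``pooled_mean``,
        ``pooled_sd``, ``pooled_median`` (NaN when unavailable).
    per_biopsy
        Long table (sample_id, cohort, sex, level, value) of each biopsy's
        own percentiles; ``None`` for tables built from published
        reference constants, where biopsy-level data are not available.
    """

    cells: pd.DataFrame
    per_biopsy: pd.DataFrame | None = None
    levels: tuple[int, ...] = PERCENTILE_LEVELS

    def cell(self, cohort: str, sex: str) -> pd.Series:
        cid = canonical_cohort_id(cohort)
        s = normalize_sex(sex)
        sel = self.cells[(self.cells["cohort"] == cid) & (self.cells["sex"] == s)]
        if sel.empty:
            raise KeyError(f"normative table has no ({cid}, {s}) cell")
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def build_normative_table(samples: Iterable[BiopsySample]) -> NormativeTable:
    """Build a two-stage normative table from biopsy samples.

    Each biopsy's own 5/25/50/75/95th minFeret percentiles are computed
    first; a (cohort, sex) cell then reports the mean and SD of those
    per-biopsy percentiles across its biopsies, plus pooled fiber-level
    mean/SD/median. Cells with a single biopsy report no SD.
    """
    samples = list(samples)
    bad = [s.sample_id for s in samples if s.n_fibers < 1]
    if bad:
        raise ValueError(f"samples without fibers: {bad}")

    rows = []
    for s in samples:
        cid = assign_cohort(s.age_months)
        pcts = biopsy_percentiles(s.minferet)
        for level, value in zip(PERCENTILE_LEVELS, pcts):
            rows.append(
                {"sample_id": s.sample_id, "cohort": cid, "sex": s.sex,
                 "level": level, "value": float(value)}
            )
    per_biopsy = pd.DataFrame(rows)

    cells = []
    pooled: dict[tuple[str, str], np.ndarray] = {}
    for s in samples:
        key = (assign_cohort(s.age_months), s.sex)
        pooled.setdefault(key, [])
        pooled[key].append(s.minferet)

    for (cid, sex), fiber_lists in sorted(
        pooled.items(), key=lambda kv: (COHORT_IDS.index(kv[0][0]), kv[0][1])
    ):
        cell: dict[str, object] = {"cohort": cid, "sex": sex, "n_biopsies": len(fiber_lists)}
        sub = per_biopsy[(per_biopsy["cohort"] == cid) & (per_biopsy["sex"] == sex)]
        for level in PERCENTILE_LEVELS:
            vals = sub.loc[sub["level"] == level, "value"].to_numpy()
            cell[f"p{level}_mean"] = float(np.mean(vals))
            # SD across biopsies is undefined for a single biopsy
            cell[f"p{level}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        allv = np.concatenate(fiber_lists)
        cell["n_fibers"] = int(allv.size)
        cell["pooled_mean"] = float(np.mean(allv))
        cell["pooled_sd"] = float(np.std(allv, ddof=1)) if allv.size > 1 else np.nan
        cell["pooled_median"] = float(np.median(allv))
        cells.append(cell)

    return NormativeTable(cells=pd.DataFrame(cells), per_biopsy=per_biopsy)


def load_reference_normative_table() -> NormativeTable:
    """The published normative table as a :class:`NormativeTable`.

    Cell percentile summaries come from the packaged per-biopsy percentile
    reference; pooled fiber statistics from the packaged cohort table.
    Per-biopsy data are not available for the reference, so
    :func:`compare_sexes` is not applicable to this table.
    """
    pct = load_sex_percentiles()
    pooled = load_cohort_stats()
    cells = []
    for (cid, sex), sub in pct.groupby(["cohort", "sex"], sort=False):
        cell = {"cohort": cid, "sex": sex}
        for _, r in sub.iterrows():
            cell[f"p{int(r['level'])}_mean"] = float(r["mean_um"])
            cell[f"p{int(r['level'])}_sd"] = float(r["sd_um"]) if pd.notna(r["sd_um"]) else np.nan
        prow = pooled[(pooled["cohort"] == cid) & (pooled["sex"] == sex)].iloc[0]
        cell["n_biopsies"] = int(prow["n_biopsies"])
        cell["n_fibers"] = int(prow["n_fibers"])
        cell["pooled_mean"] = float(prow["mean_um"])
        cell["pooled_sd"] = float(prow["sd_um"])
        cell["pooled_median"] = float(prow["median_um"])
        cells.append(cell)
    df = pd.DataFrame(cells)
    df["cohort"] = pd.Categorical(df["cohort"], categories=COHORT_IDS, ordered=True)
    df = df.sort_values(["cohort", "sex"]).reset_index(drop=True)
    df["cohort"] = df["cohort"].astype(str)
    return NormativeTable(cells=df, per_biopsy=None)


def compare_sexes(table: NormativeTable, cohort: str, level: int) -> dict:
    """Welch two-sided test of male vs female per-biopsy percentiles.

    Returns ``{"difference": male_mean - female_mean, "p_value": p,
    "n_male": ..., "n_female": ...}``. Requires at least two biopsies per
    sex in the cell; otherwise raises ``ValueError("not estimable ...")``.
    """
    if table.per_biopsy is None:
        raise ValueError("not estimable: table has no per-biopsy data")
    cid = canonical_cohort_id(cohort)
    if level not in table.levels:
        raise ValueError(f"level {level} not among table levels {table.levels}")
    sub = table.per_biopsy[(table.per_biopsy["cohort"] == cid) & (table.per_biopsy["level"] == level)]
    male = sub.loc[sub["sex"] == "male", "value"].to_numpy()
    female = sub.loc[sub["sex"] == "female", "value"].to_numpy()
    if len(male) < 2 or len(female) < 2:
        raise ValueError(
            f"not estimable: need >= 2 biopsies per sex in ({cid}, level {level}); "
            f"have {len(male)} male, {len(female)} female"
        )
    diff = float(np.mean(male) - np.mean(female))
    if np.allclose(male.std(), 0) and np.allclose(female.std(), 0) and np.isclose(diff, 0):
        p = 1.0  # identical constant groups: no evidence of a difference
    else:
        p = float(sps.ttest_ind(male, female, equal_var=False).pvalue)
    return {"difference": diff, "p_value": p, "n_male": len(male), "n_female": len(female)}


def export_growth_curves(table: NormativeTable, split: str = "by-sex") -> pd.DataFrame:
    """Long-format growth-curve table (cohort, group, level, value_um).

    ``split="by-sex"`` keeps male and female rows separate throughout.
    ``split="pooled-under-2y"`` merges the sexes for cohorts through
    "2 years" (fiber growth shows no sex effect there), weighting each
    sex's percentile mean by its biopsy count, and keeps sex-specific rows
    for older cohorts.
    """
    if split not in ("by-sex", "pooled-under-2y"):
        raise ValueError(f"unknown split {split!r}")
    rows = []
    cells = table.cells
    for cid in COHORT_IDS:
        sub = cells[cells["cohort"] == cid]
        if sub.empty:
            continue
        if split == "pooled-under-2y" and cid in POOLED_UNDER_2Y:
            weights = sub["n_biopsies"].to_numpy(dtype=float)
            for level in table.levels:
                vals = sub[f"p{level}_mean"].to_numpy(dtype=float)
                rows.append(
                    {"cohort": cid, "group": "pooled", "level": level,
                     "value_um": float(np.average(vals, weights=weights))}
                )
        else:
            for _, r in sub.iterrows():
                for level in table.levels:
                    rows.append(
                        {"cohort": cid, "group": r["sex"], "level": level,
                         "value_um": float(r[f"p{level}_mean"])}
                    )
    return pd.DataFrame(rows, columns=["cohort", "group", "level", "value_um"])
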