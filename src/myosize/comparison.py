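"""Compare a query biopsy against its age/sex normative cohort.

A query biopsy's 5/25/50/75/95th minFeret percentiles are expressed as
z-scores against the normative per-biopsy percentile means and SDs of the
matched cohort cell. Two pattern indices follow:

* **shift index** — query median / normative mean median: < 1 means
  smaller fibers overall;
* **dispersion index** — query IQR (p75 − p25) / normative mean IQR:
  > 1 means wider size variation.

Pattern flags operationalize the two classic disease patterns: uniform
smallness (all percentiles >= 2 SD below normal with near-normal
dispersion — the myotubular-myopathy-like picture) and excess variation
(dispersion index >= 1.5 with a normal median — the dystrophy-like
picture). The thresholds (z <= −2, dispersion >= 1.5) are this package's
operationalization of qualitative patterns, and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import cumulative_probability
from .norms import NormativeTable, assign_cohort, biopsy_percentiles
from .reference import PERCENTILE_LEVELS
from .samples import BiopsySample

Z_SMALL = -2.0
DISPERSION_HIGH = 1.5


@dataclass
class ComparisonReport:
    """Query-vs-norms metrics for one biopsy.

    ``levels`` rows: level, query value, normative mean, normative SD,
    z-score. The pattern flag is one of within-normal, uniform-smallness,
    excess-variation, mixed.
    """

    cohort: str
    sex: str
    levels: pd.DataFrame
    shift_index: float
    dispersion_index: float
    pattern: str

    def to_json_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "sex": self.sex,
            "shift_index": self.shift_index,
            "dispersion_index": self.dispersion_index,
            "pattern": self.pattern,
            "levels": self.levels.to_dict(orient="records"),
        }


def compare_to_norms(
    query: BiopsySample,
    table: NormativeTable,
    z_small: float = Z_SMALL,
    dispersion_high: float = DISPERSION_HIGH,
) -> ComparisonReport:
    """Compare a query biopsy against its matched normative cohort cell.

    z(level) = (query percentile − normative mean) / normative SD, the
    shift index is the query median over the normative mean median, and
    the dispersion index the query IQR over the normative mean IQR.
    Raises ``KeyError`` when the matched (cohort, sex) cell is absent.
    """
    cohort = assign_cohort(query.age_months)
    cell = table.cell(cohort, query.sex)
    q = biopsy_percentiles(query.minferet, PERCENTILE_LEVELS)

    rows = []
    zs = {}
    for level, qv in zip(PERCENTILE_LEVELS, q):
        mean = float(cell[f"p{level}_mean"])
        sd = float(cell[f"p{level}_sd"])
        z = (qv - mean) / sd if np.isfinite(sd) and sd > 0 else np.nan
        zs[level] = z
        rows.append(
            {"level": level, "query_um": float(qv), "norm_mean_um": mean,
             "norm_sd_um": sd, "z": z}
        )
    levels = pd.DataFrame(rows)

    shift = float(q[PERCENTILE_LEVELS.index(50)]) / float(cell["p50_mean"])
    norm_iqr = float(cell["p75_mean"]) - float(cell["p25_mean"])
    query_iqr = float(q[PERCENTILE_LEVELS.index(75)] - q[PERCENTILE_LEVELS.index(25)])
    dispersion = query_iqr / norm_iqr

    finite_z = [z for z in zs.values() if np.isfinite(z)]
    all_small = len(finite_z) == len(zs) and all(z <= z_small for z in finite_z)
    dispersed = dispersion >= dispersion_high and (
        not np.isfinite(zs[50]) or abs(zs[50]) < abs(z_small)
    )
    if all_small and dispersion >= dispersion_high:
        pattern = "mixed"
    elif all_small:
        pattern = "uniform-smallness"
    elif dispersed:
        pattern = "excess-variation"
    else:
        pattern = "within-normal"

    return ComparisonReport(
        cohort=cohort, sex=query.sex, levels=levels,
        shift_index=shift, dispersion_index=dispersion, pattern=pattern,
    )


def curve_band_fraction(query: BiopsySample, cohort_samples: list[BiopsySample], n_grid: int = 200) -> float:
    """Fraction of grid points where the query curve lies inside the
    cohort's min-max cumulative-probability band (a visual-free check of
    the overlay plot)."""
    if not cohort_samples:
        raise ValueError("cohort is empty")
    all_sizes = np.concatenate([s.minferet for s in cohort_samples] + [query.minferet])
    grid = np.linspace(all_sizes.min(), all_sizes.max(), n_grid)
    qc = cumulative_probability(query.minferet)
    qp = np.array([qc.probability_at(x) for x in grid])
    cohort_p = []
    for s in cohort_samples:
        c = cumulative_probability(s.minferet)
        cohort_p.append([c.probability_at(x) for x in grid])
    cohort_p = np.asarray(cohort_p)
    lo, hi = cohort_p.min(axis=0), cohort_p.max(axis=0)
    inside = (qp >= lo - 1e-12) & (qp <= hi + 1e-12)
    return float(inside.mean())


def overlay_curves(query: BiopsySample, cohort_samples: list[BiopsySample], path) -> None:
    """Write a cumulative-curve overlay: cohort biopsies plus the query.

    The query is drawn dark red and thick over the sex-colored cohort
    curves. Deterministic for fixed inputs.
    """
    if not cohort_samples:
        raise ValueError("cohort is empty")
    from .distributions import plot_cumulative_curves

    curves = {s.sample_id: cumulative_probability(s.minferet) for s in cohort_samples}
    curves[query.sample_id] = cumulative_probability(query.minferet)
    sexes = {s.sample_id: s.sex for s in cohort_samples}
    plot_cumulative_curves(curves, path, sexes=sexes, highlight=query.sample_id)
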