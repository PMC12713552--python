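"""Core sample containers shared across the pipeline.

A :class:`BiopsySample` bundles biopsy metadata (age in completed months,
sex, muscle site) with its per-fiber measurement table. Fiber tables are
plain :class:`pandas.DataFrame` objects using the same column dialect the
per-fiber CSV exports use (``label_id``, ``area_um2``, ``minferet_um``,
optionally ``x_um``/``y_um`` centroids and filter flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical fiber-table columns, in export order
FIBER_COLUMNS = ["label_id", "area_um2", "minferet_um"]

VALID_SEXES = ("female", "male")


def normalize_sex(sex: str) -> str:
    """Map common spellings (``M``, ``m``, ``Male`` ...) onto {male, female}."""
    s = str(sex).strip().lower()
    if s in ("f", "female", "girl", "woman"):
        return "female"
    if s in ("m", "male", "boy", "man"):
        return "male"
    raise ValueError(f"unrecognized sex {sex!r}; expected male or female")


@dataclass
class BiopsySample:
    """One biopsy: metadata plus its fiber measurement table.

    Parameters
    ----------
    sample_id
        Unique identifier for the biopsy.
    age_months
        Age at biopsy in real-valued completed months (0 <= age < 312).
    sex
        ``"male"`` or ``"female"`` (normalized on construction).
    fibers
        Per-fiber table with at least ``area_um2`` and ``minferet_um``.
    muscle_site
        Free-text biopsy location (quadriceps, vastus lateralis, ...).
    """

    sample_id: str
    age_months: float
    sex: str
    fibers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FIBER_COLUMNS))
    muscle_site: str = "unknown"

    def __post_init__(self) -> None:
        self.sex = normalize_sex(self.sex)
        self.age_months = float(self.age_months)
        if not 0 <= self.age_months < 312:
            raise ValueError(
                f"age {self.age_months} months outside the study range [0, 312)"
            )
        missing = [c for c in ("area_um2", "minferet_um") if c not in self.fibers.columns]
        if len(self.fibers) and missing:
            raise ValueError(f"fiber table missing required column(s): {missing}")

    @property
    def minferet(self) -> np.ndarray:
        """minFeret diameters (μm) as a float array."""
        return np.asarray(self.fibers["minferet_um"], dtype=float)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def with_fibers(self, fibers: pd.DataFrame) -> "BiopsySample":
        """Return a copy of this sample carrying a different fiber table."""
        return BiopsySample(
            sample_id=self.sample_id,
            age_months=self.age_months,
            sex=self.sex,
            fibers=fibers,
            muscle_site=self.muscle_site,
        )
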