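"""Manual-vs-automated agreement protocol.

Automated fiber measurements are validated against manual measurements of
the same region by comparing seven size percentiles (minimum, 10th, 25th,
50th, 75th, 90th, maximum) plus the total fiber count. Differences use
the symmetric percent difference, 100·(auto − manual)/((auto + manual)/2)
— the formula that exactly reproduces the published count-row percent
differences — and the acceptance criterion is |difference| <= 15% at
every size percentile (counts are reported but not part of the
criterion, since region-of-interest matching is inexact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALIDATION_LEVELS = (0, 10, 25, 50, 75, 90, 100)
LEVEL_NAMES = {0: "Minimum", 10: "10th", 25: "25th", 50: "50th", 75: "75th",
               90: "90th", 100: "Maximum"}
DEFAULT_THRESHOLD = 15.0  # percent


def percent_difference(manual: float, automated: float) -> float:
    """Symmetric percent difference, 100·(auto − manual)/mean(auto, manual).

    Antisymmetric under swapping the arguments and invariant to a common
    scale factor. Undefined when both values are zero.
    """
    m, a = float(manual), float(automated)
    if m == 0 and a == 0:
        raise ValueError("percent difference undefined when both values are zero")
    return 100.0 * (a - m) / ((a + m) / 2.0)


@dataclass
class ValidationReport:
    """Manual-vs-automated comparison at the size percentiles and count.

    ``table`` rows: percentile label, manual value, automated value,
    percent difference (one decimal), pass flag. ``passed`` is True iff
    every size percentile agrees within the threshold.
    """

    table: pd.DataFrame
    threshold: float
    passed: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def agreement_report(
    manual_values, automated_values, threshold: float = DEFAULT_THRESHOLD
) -> ValidationReport:
    """Compare two per-fiber minFeret vectors measured on the same region.

    Computes the seven size percentiles for each vector, their symmetric
    percent differences, and the total-count difference; the overall pass
    flag requires every size percentile within ``threshold`` percent.
    """
    m = np.asarray(manual_values, dtype=float)
    a = np.asarray(automated_values, dtype=float)
    if m.size == 0 or a.size == 0:
        raise ValueError("both measurement sets must be nonempty")
    mp = np.percentile(m, VALIDATION_LEVELS, method="linear")
    ap = np.percentile(a, VALIDATION_LEVELS, method="linear")
    rows = []
    for level, mv, av in zip(VALIDATION_LEVELS, mp, ap):
        pd_ = percent_difference(mv, av)
        rows.append(
            {
                "percentile": LEVEL_NAMES[level],
                "manual": float(mv),
                "automated": float(av),
                "pct_diff": round(pd_, 1),
                "within_threshold": bool(abs(pd_) <= threshold),
            }
        )
    count_pd = percent_difference(m.size, a.size)
    rows.append(
        {
            "percentile": "Total number",
            "manual": float(m.size),
            "automated": float(a.size),
            "pct_diff": round(count_pd, 1),
            # counts are excluded from the acceptance criterion
            "within_threshold": None,
        }
    )
    table = pd.DataFrame(rows)
    size_rows = table["percentile"] != "Total number"
    passed = bool(table.loc[size_rows, "within_threshold"].all())
    return ValidationReport(table=table, threshold=threshold, passed=passed)
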