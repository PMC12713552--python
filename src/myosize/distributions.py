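"""Cumulative-probability curves, frequency histograms, summary statistics.

A biopsy's fiber-size distribution is summarized three ways: an empirical
cumulative-probability curve (P(size <= x) against sorted sizes — a
rightward shift means larger fibers, a shallow slope means greater size
variation), a frequency histogram in fixed-width bins of 5 μm anchored at
zero, and summary statistics (mean, sample SD, median, and percentiles
by linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SUMMARY_LEVELS = (0, 5, 10, 25, 50, 75, 90, 95, 100)


@dataclass(frozen=True)
class CumulativeCurve:
    """Empirical cumulative curve: sorted sizes with probabilities i/n."""

    sizes: np.ndarray
    probabilities: np.ndarray

    def probability_at(self, x: float) -> float:
        """P(fiber size <= x)."""
        return float(np.searchsorted(self.sizes, x, side="right")) / len(self.sizes)


@dataclass(frozen=True)
class SummaryStats:
    """Summary of one measurement vector (all sizes in μm)."""

    n: int
    mean: float
    sd: float
    median: float
    percentiles: dict[int, float]

    def as_dict(self) -> dict:
        d = {"n": self.n, "mean": self.mean, "sd": self.sd, "median": self.median}
        d.update({f"p{k}": v for k, v in self.percentiles.items()})
        return d


def cumulative_probability(values) -> CumulativeCurve:
    """Empirical cumulative-probability curve over the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot build a cumulative curve from no measurements")
    probs = np.arange(1, v.size + 1, dtype=float) / v.size
    return CumulativeCurve(sizes=v, probabilities=probs)


def histogram(values, bin_width: float = 5.0) -> pd.DataFrame:
    """Frequency histogram in half-open bins [k*w, (k+1)*w) anchored at 0.

    Returns a table (bin_left, bin_right, count); counts sum to n. An
    empty input yields an explicit empty table with zero bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    if (v < 0).any():
        raise ValueError("negative sizes are not meaningful")
    idx = np.floor(v / bin_width).astype(int)  # half-open bins by construction
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    left = np.arange(n_bins) * bin_width
    return pd.DataFrame({"bin_left": left, "bin_right": left + bin_width, "count": counts})


def summarize(values, levels=SUMMARY_LEVELS) -> SummaryStats:
    """Summary statistics: mean, sample SD (n-1), median, percentiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize no measurements")
    pct = np.percentile(v, levels, method="linear")
    return SummaryStats(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        percentiles={int(l): float(p) for l, p in zip(levels, pct)},
    )


def plot_cumulative_curves(curves: dict, path, sexes: dict | None = None, highlight: str | None = None) -> None:
    """Overlay one cumulative curve per biopsy, colored by sex.

    ``curves`` maps sample id to :class:`CumulativeCurve`; ``sexes``
    optionally maps sample id to "male" (blue) or "female" (red). A
    ``highlight`` sample is drawn thicker and dark red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"male": "tab:blue", "female": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for sid, curve in curves.items():
        if highlight is not None and sid == highlight:
            ax.step(curve.sizes, curve.probabilities, color="darkred", lw=2.2, zorder=3, label=sid)
        else:
            c = colors.get((sexes or {}).get(sid, ""), "0.6")
            ax.step(curve.sizes, curve.probabilities, color=c, lw=0.9, alpha=0.8)
    ax.set_xlabel("minFeret diameter (μm)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.02)
    if highlight is not None:
        ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_histogram(values, path, bin_width: float = 5.0) -> None:
    """Write a frequency-histogram figure (bins of ``bin_width`` μm)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = histogram(values, bin_width)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(h["bin_left"], h["count"], width=bin_width, align="edge",
           color="lightcoral", edgecolor="white")
    ax.set_xlabel("minFeret diameter (μm)")
    ax.set_ylabel("fiber count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
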