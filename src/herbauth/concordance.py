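"""Concordance between NGS read percentages and ddPCR copy percentages.

For each species the paired observations (copy%, read%) across samples
are summarised by a Pearson correlation and an ordinary least-squares
regression of read% (the compositional proxy under scrutiny) on copy%
(the reference measurement).  A slope far from 1 — or a correlation near
0 — quantifies how unreliable read counts are as a proxy for the actual
species content.  A sign test on read% − copy% classifies the direction
of systematic reporting bias.

Statistics are computed on the linear scale; logarithmic axes in the
scatter export are presentation only.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcordancePoint",
    "ConcordanceStats",
    "concordance_stats",
    "reporting_bias",
    "scatter_export",
]


@dataclass(frozen=True)
class ConcordancePoint:
    sample_id: str
    species: str
    read_pct: float
    copy_pct: float

    def __post_init__(self) -> None:
        for v in (self.read_pct, self.copy_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class ConcordanceStats:
    """Per-species summary: n, Pearson r, OLS slope/intercept, p-value.

    The regression is read% = intercept + slope · copy%.  For simple
    regression the p-value of the slope and of the correlation
    coefficient coincide.  Degenerate inputs (zero variance on an axis)
    leave r/p as NaN with a flag; a constant read% still has a defined
    slope of 0.
    """

    species: str
    n: int
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    flags: frozenset[str] = frozenset()


def concordance_stats(points: Sequence[ConcordancePoint]) -> ConcordanceStats:
    """Correlation and regression of read% on copy% for one species."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    species = {p.species for p in points}
    if len(species) != 1:
        raise ValueError(f"points must share one species, got {sorted(species)}")
    x = np.array([p.copy_pct for p in points])
    y = np.array([p.read_pct for p in points])
    flags: set[str] = set()
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        flags.add("degenerate_both_constant")
        r = slope = intercept = p_val = math.nan
        intercept = float(y[0])
        slope = 0.0
    elif np.ptp(x) == 0.0:
        flags.add("degenerate_constant_copy_pct")
        r = p_val = slope = math.nan
        intercept = math.nan
    elif np.ptp(y) == 0.0:
        flags.add("degenerate_constant_read_pct")
        r = p_val = math.nan
        slope, intercept = 0.0, float(y[0])
    else:
        fit = stats.linregress(x, y)
        r, slope, intercept, p_val = (
            float(fit.rvalue), float(fit.slope), float(fit.intercept),
            float(fit.pvalue),
        )
    return ConcordanceStats(
        species=points[0].species, n=len(points), pearson_r=r,
        slope=slope, intercept=intercept, p_value=p_val,
        flags=frozenset(flags),
    )


def reporting_bias(
    points: Sequence[ConcordancePoint], alpha: float = 0.05
) -> str:
    """Sign-test classification of systematic reporting bias.

    ``over`` — read% significantly exceeds copy% (the species is
    over-reported among the reads); ``under`` — the reverse; ``none``
    otherwise.  Ties (read% == copy%) are dropped, as usual for a sign
    test.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    diffs = [p.read_pct - p.copy_pct for p in points]
    nonzero = [d for d in diffs if d != 0.0]
    if not nonzero:
        return "none"
    k_over = sum(d > 0 for d in nonzero)
    n = len(nonzero)
    if stats.binomtest(k_over, n, 0.5, alternative="greater").pvalue < alpha:
        return "over"
    if stats.binomtest(k_over, n, 0.5, alternative="less").pvalue < alpha:
        return "under"
    return "none"


def scatter_export(
    points: Sequence[ConcordancePoint],
    plot_path,
    csv_path,
    log_axes: bool = True,
) -> None:
    """Write a per-species read% vs copy% scatter plot and a tidy CSV.

    On log axes, zero percentages are drawn at half the smallest positive
    value on that axis (annotated in the legend); the CSV always carries
    the raw values, one row per input point.
    """
    if not points:
        raise ValueError("no points to plot")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "species", "read_pct", "copy_pct"])
        for p in points:
            writer.writerow([p.sample_id, p.species, f"{p.read_pct:.4f}",
                             f"{p.copy_pct:.4f}"])

    x = np.array([p.copy_pct for p in points])
    y = np.array([p.read_pct for p in points])
    pseudo_note = ""
    if log_axes:
        def _pseudo(v: np.ndarray) -> tuple[np.ndarray, float | None]:
            pos = v[v > 0]
            if pos.size == 0 or (v > 0).all():
                return v, None
            pc = pos.min() / 2.0
            return np.where(v == 0, pc, v), pc

        x, pc_x = _pseudo(x)
        y, pc_y = _pseudo(y)
        notes = [f"{ax}=0 at {pc:g}" for ax, pc in
                 [("copy%", pc_x), ("read%", pc_y)] if pc is not None]
        if notes:
            pseudo_note = " (zeros drawn at pseudo-count: " + ", ".join(notes) + ")"

    fig, ax = plt.subplots(figsize=(5, 5))
    for species in sorted({p.species for p in points}):
        mask = np.array([p.species == species for p in points])
        ax.scatter(x[mask], y[mask], label=species, alpha=0.7)
    if log_axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("ddPCR copy %")
    ax.set_ylabel("NGS read %")
    ax.set_title("Read share vs copy share" + pseudo_note, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
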