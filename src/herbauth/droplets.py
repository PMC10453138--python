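"""Droplet calling: classify ddPCR droplets as positive or negative.

A droplet digital PCR well partitions a reaction into ~20,000 nanolitre
droplets; after end-point amplification each droplet reports a single
fluorescence amplitude per channel.  Droplets containing at least one
template copy amplify to a high-amplitude "positive" population, empty
droplets stay in a low "negative" population, and partially amplified
droplets ("rain") land in between.  This module assigns every droplet to
one of the two classes from the one-dimensional amplitude distribution:

1. a binned kernel density estimate of the amplitudes (histogram smoothed
   with a Gaussian kernel at a Silverman-derived bandwidth),
2. the threshold is placed at the density valley between the two dominant
   modes,
3. droplets in the "rain" band between the robust population centres
   (median ± k·MAD) are reassigned to the nearest centre in robust
   z-distance.

Droplets exactly at the threshold are called negative — the conservative
choice when a positive call supports a contamination claim.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "DropletSet",
    "CallOptions",
    "DropletCall",
    "LowDropletCountError",
    "call_droplets",
    "threshold_oracle",
    "OracleSplit",
    "read_amplitude_csv",
    "write_amplitude_csv",
]


class LowDropletCountError(ValueError):
    """Raised when a well has too few droplets for density estimation."""


@dataclass
class DropletSet:
    """Raw per-droplet amplitudes for one well and channel.

    ``true_labels`` (positive = True) is only available for simulated
    wells and is never consulted by the caller; it exists so that calling
    accuracy can be measured against ground truth.
    """

    well_id: str
    channel: int
    amplitudes: np.ndarray
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise ValueError("amplitudes must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=bool)
            if self.true_labels.shape != self.amplitudes.shape:
                raise ValueError("true_labels must match amplitudes in length")

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass(frozen=True)
class CallOptions:
    """Tunables for :func:`call_droplets`.

    min_droplets
        Floor below which calling refuses to run (density estimation is
        meaningless on a handful of droplets).
    bw_adjust
        Multiplier on the Silverman bandwidth; < 1 sharpens the density so
        well-separated modes are not smoothed into one.
    min_peak_prominence
        Peaks below this fraction of the tallest mode are ignored.
    valley_ratio_max
        A two-mode split is accepted only if the density at the valley is
        below this fraction of the smaller peak; shallow valleys (noise
        wiggles on one population) are rejected.
    outlier_k, min_minority
        Minority-cluster rescue: when the density shows a single mode, at
        least ``min_minority`` droplets beyond ``median ± outlier_k·MAD``
        of the dominant population are still called as the opposite
        class.  This catches the routine ddPCR regime of a positive
        cluster far too small to raise a density mode, while a handful of
        tail stragglers never flips a well.
    rain_k
        Width of the robust population bands, in MADs: droplets between
        ``median_neg + k·MAD`` and ``median_pos − k·MAD`` count as rain
        and are reassigned by robust distance.
    negative_band
        Amplitude interval in which a single-population well is
        interpreted as all-negative; one outside it is called
        all-positive.
    """

    min_droplets: int = 100
    grid_size: int = 512
    bw_adjust: float = 0.5
    min_peak_prominence: float = 0.02
    valley_ratio_max: float = 0.5
    outlier_k: float = 7.0
    min_minority: int = 3
    rain_k: float = 5.0
    negative_band: tuple[float, float] = (0.0, 5000.0)


@dataclass(frozen=True)
class DropletCall:
    """Result of calling one well: class counts, threshold and QC flags."""

    well_id: str
    channel: int
    n_total: int
    n_positive: int
    n_negative: int
    threshold: float | None
    n_rain_reassigned: int
    quality_flags: frozenset[str] = frozenset()
    positive_mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative != self.n_total:
            raise ValueError("class counts must sum to n_total")
        if min(self.n_positive, self.n_negative) < 0:
            raise ValueError("counts must be non-negative")


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    std = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(std, iqr / 1.349) if iqr > 0 else std
    return 0.9 * scale * n ** (-1 / 5)


def _density(x: np.ndarray, options: CallOptions) -> tuple[np.ndarray, np.ndarray]:
    """Binned KDE: histogram + Gaussian smoothing on a regular grid."""
    bw = _silverman_bandwidth(x) * options.bw_adjust
    lo, hi = float(x.min()), float(x.max())
    pad = max(3.0 * bw, 1e-9 * max(abs(lo), abs(hi), 1.0))
    edges = np.linspace(lo - pad, hi + pad, options.grid_size + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    sigma_bins = max(bw / bin_width, 0.5)
    density = gaussian_filter1d(counts.astype(float), sigma=sigma_bins, mode="constant")
    return centers, density


def _robust_center(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, mad


def call_droplets(droplets: DropletSet, options: CallOptions | None = None) -> DropletCall:
    """Assign every droplet in a well to the positive or negative class.

    Deterministic for fixed input and options.  Raises
    :class:`LowDropletCountError` below ``options.min_droplets``; a
    constant-amplitude or unimodal well is called as a single population
    with a quality flag rather than crashing.
    """
    opts = options or CallOptions()
    a = droplets.amplitudes
    n = a.size
    if n < opts.min_droplets:
        raise LowDropletCountError(
            f"well {droplets.well_id}: {n} droplets < floor of {opts.min_droplets}"
        )

    flags: set[str] = set()

    if np.ptp(a) == 0.0:
        flags.update({"constant_amplitude", "unimodal"})
        return _single_population_call(droplets, float(a[0]), opts, flags)

    centers, density = _density(a, opts)
    peaks, _ = find_peaks(density, prominence=opts.min_peak_prominence * density.max())
    threshold: float | None = None
    if peaks.size >= 2:
        # Sampling noise can raise several shallow peaks within one
        # population, so consider every gap between adjacent peaks and
        # pick the valley that is deepest relative to the tallest peak on
        # each side; accept it only if genuinely deep.
        best_sse = np.inf
        for i in range(peaks.size - 1):
            lo_pk, hi_pk = int(peaks[i]), int(peaks[i + 1])
            valley = lo_pk + int(np.argmin(density[lo_pk : hi_pk + 1]))
            left_max = float(density[peaks[: i + 1]].max())
            right_max = float(density[peaks[i + 1 :]].max())
            if density[valley] > opts.valley_ratio_max * min(left_max, right_max):
                continue
            # among acceptably deep valleys, keep the split that best
            # separates the data (smallest pooled within-class variance)
            cand = float(centers[valley])
            neg, pos = a[a <= cand], a[a > cand]
            if neg.size == 0 or pos.size == 0:
                continue
            sse = float(((neg - neg.mean()) ** 2).sum()
                        + ((pos - pos.mean()) ** 2).sum())
            if sse < best_sse:
                best_sse, threshold = sse, cand

    if threshold is None:
        # single dominant population: look for a minority cluster in either
        # far tail; droplets above the dominant population are positives,
        # droplets below it mean the dominant population itself is positive
        mode = float(centers[int(np.argmax(density))])
        med, mad = _robust_center(a)
        mad = max(mad, 1e-12)
        cut_high = med + opts.outlier_k * mad
        cut_low = med - opts.outlier_k * mad
        n_high = int(np.count_nonzero(a > cut_high))
        n_low = int(np.count_nonzero(a < cut_low))
        if n_high >= opts.min_minority and n_high >= n_low:
            flags.add("minority_cluster")
            threshold = float(cut_high)
        elif n_low >= opts.min_minority:
            flags.add("minority_cluster")
            threshold = float(cut_low)
        else:
            flags.add("unimodal")
            return _single_population_call(droplets, mode, opts, flags)

    positive = a > threshold  # droplets at the threshold are negative
    n_rain = 0
    if positive.any() and (~positive).any():
        med_neg, mad_neg = _robust_center(a[~positive])
        med_pos, mad_pos = _robust_center(a[positive])
        lo = med_neg + opts.rain_k * mad_neg
        hi = med_pos - opts.rain_k * mad_pos
        if lo < hi:
            rain = (a > lo) & (a < hi)
            if rain.any():
                flags.add("rain")
                eps = 1e-12
                z_neg = np.abs(a[rain] - med_neg) / max(mad_neg, eps)
                z_pos = np.abs(a[rain] - med_pos) / max(mad_pos, eps)
                new_pos = z_pos < z_neg  # tie goes to negative
                n_rain = int(np.count_nonzero(new_pos != positive[rain]))
                positive[rain] = new_pos

    n_pos = int(np.count_nonzero(positive))
    return DropletCall(
        well_id=droplets.well_id,
        channel=droplets.channel,
        n_total=n,
        n_positive=n_pos,
        n_negative=n - n_pos,
        threshold=threshold,
        n_rain_reassigned=n_rain,
        quality_flags=frozenset(flags),
        positive_mask=positive,
    )


def _single_population_call(
    droplets: DropletSet, mode: float, opts: CallOptions, flags: set[str]
) -> DropletCall:
    lo, hi = opts.negative_band
    all_negative = lo <= mode <= hi
    n = len(droplets)
    mask = np.full(n, not all_negative, dtype=bool)
    return DropletCall(
        well_id=droplets.well_id,
        channel=droplets.channel,
        n_total=n,
        n_positive=0 if all_negative else n,
        n_negative=n if all_negative else 0,
        threshold=None,
        n_rain_reassigned=0,
        quality_flags=frozenset(flags),
        positive_mask=mask,
    )


@dataclass(frozen=True)
class OracleSplit:
    threshold: float | None
    positive_mask: np.ndarray
    degenerate: bool = False


def threshold_oracle(amplitudes: Sequence[float] | np.ndarray) -> OracleSplit:
    """Brute-force two-class split minimising total within-class variance.

    Scans every midpoint between consecutive sorted unique amplitudes and
    returns the split with the smallest pooled sum of squared deviations.
    O(u·n); intended as an independent test oracle for small wells, not as
    a production caller.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 droplets")
    uniq = np.unique(a)
    if uniq.size < 2:
        return OracleSplit(None, np.zeros(a.size, dtype=bool), degenerate=True)
    best_sse = np.inf
    best_thr = None
    for left, right in zip(uniq[:-1], uniq[1:]):
        thr = 0.5 * (left + right)
        neg = a[a <= thr]
        pos = a[a > thr]
        sse = float(np.sum((neg - neg.mean()) ** 2) + np.sum((pos - pos.mean()) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_thr = thr
    return OracleSplit(best_thr, a > best_thr)


def read_amplitude_csv(path) -> list[DropletSet]:
    """Read a droplet amplitude export (columns: well, channel, amplitude)."""
    groups: dict[tuple[str, int], list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"well", "channel", "amplitude"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"amplitude CSV must have columns {sorted(required)}")
        for row in reader:
            key = (row["well"], int(row["channel"]))
            groups.setdefault(key, []).append(float(row["amplitude"]))
    return [
        DropletSet(well_id=w, channel=c, amplitudes=np.array(v))
        for (w, c), v in groups.items()
    ]


def write_amplitude_csv(droplet_sets: Iterable[DropletSet], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "channel", "amplitude"])
        for ds in droplet_sets:
            for amp in ds.amplitudes:
                writer.writerow([ds.well_id, ds.channel, f"{amp:.4f}"])
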