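"""Synthetic data generators with the statistical structure the analysis assumes.

The market-survey samples behind the original study are physical
specimens; nothing here tries to imitate a specific herb lot.  Instead,
each generator reproduces the *mechanism* a downstream stage relies on:

* droplet wells — template molecules partition into droplets following a
  Poisson law, so the number of copies in a droplet is Poisson(λ) and
  the fraction of empty (negative) droplets is e^{−λ};
* fluorometry — four replicate readings (two dilutions × two standard
  curves) with multiplicative, lognormal noise at a stated coefficient
  of variation, averaged into the concentration estimate;
* mixtures — gravimetric mass fractions converted to per-species target
  copies through each species' 1C genome mass;
* read tables — multinomial sampling of reads with per-species
  amplification/recovery bias, stochastic species dropout, and a
  row-stochastic misattribution matrix that re-labels reads between
  phylogenetically adjacent taxa.

Every generator is bit-reproducible under a fixed integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accounting import PG_PER_NG, SpeciesAssay
from .droplets import DropletSet
from .reads import ReadTable

__all__ = [
    "MixtureSpec",
    "DropletSimParams",
    "ReadSimParams",
    "FluorometryResult",
    "simulate_droplets",
    "simulate_fluorometry",
    "simulate_mixture_copies",
    "simulate_read_table",
    "neighbour_misattribution",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A gravimetric mixture: (species, mass fraction) pairs and total template mass.

    The default 18 ng per reaction is the standard template input of the
    PCR workflow this emulates.
    """

    components: tuple[tuple[str, float], ...]
    total_template_mass_ng: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.components]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("mass fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("mass fractions must sum to 1 within 1e-9")
        if not self.total_template_mass_ng > 0:
            raise ValueError("total_template_mass_ng must be positive")


@dataclass(frozen=True)
class DropletSimParams:
    """Two-population amplitude model for one simulated ddPCR well.

    ``lambda_true`` is the mean template copies per droplet.  Amplitudes
    are Gaussian around ``neg_mean`` / ``pos_mean``; a ``rain_fraction``
    of droplets instead get an amplitude uniform between the two means
    (partly amplified droplets).  Ground truth is occupancy ≥ 1,
    regardless of rain.  20,000 droplets per well is typical for the
    instrument class emulated.
    """

    lambda_true: float
    n_droplets: int = 20000
    neg_mean: float = 2000.0
    pos_mean: float = 8000.0
    neg_sd: float = 200.0
    pos_sd: float = 200.0
    rain_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.lambda_true, self.neg_mean, self.pos_mean, self.neg_sd,
                self.pos_sd, self.rain_fraction]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("parameters must be finite")
        if self.lambda_true < 0:
            raise ValueError("lambda_true must be >= 0")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if not self.pos_mean > self.neg_mean:
            raise ValueError("pos_mean must exceed neg_mean")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValueError("amplitude sds must be positive")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class ReadSimParams:
    """Distortion model for a metabarcoding read table.

    bias
        Per-species positive multiplier on the expected read share
        (amplification efficiency, DNA extractability, barcode recovery).
    misattribution
        Row-stochastic DataFrame: entry (i, j) is the probability a read
        that originates from taxon i is attributed to taxon j (sequencing
        errors between close relatives).  None means identity.
    dropout
        Per-species probability of yielding no reads at all (e.g. species
        whose DNA resists extraction).
    """

    total_reads: int
    bias: Mapping[str, float] = field(default_factory=dict)
    misattribution: pd.DataFrame | None = None
    dropout: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if any(b <= 0 for b in self.bias.values()):
            raise ValueError("bias multipliers must be positive")
        if any(not 0 <= d <= 1 for d in self.dropout.values()):
            raise ValueError("dropout probabilities must lie in [0, 1]")
        if self.misattribution is not None:
            m = self.misattribution
            if (m.values < 0).any():
                raise ValueError("misattribution entries must be >= 0")
            if not np.allclose(m.sum(axis=1).values, 1.0, atol=1e-9):
                raise ValueError("misattribution rows must sum to 1 within 1e-9")


@dataclass(frozen=True)
class FluorometryResult:
    replicates: tuple[float, ...]
    mean: float
    sd: float


def simulate_droplets(params: DropletSimParams, well_id: str = "A01",
                      channel: int = 1) -> DropletSet:
    """Simulate one ddPCR well under Poisson partitioning.

    Droplet occupancy ~ Poisson(lambda_true); occupied droplets draw from
    the positive amplitude population, empty ones from the negative.  A
    ``rain_fraction`` of droplets (chosen at random) get an amplitude
    uniform between the two population means while keeping their
    occupancy-derived ground-truth label.
    """
    rng = np.random.default_rng(params.seed)
    occupancy = rng.poisson(params.lambda_true, size=params.n_droplets)
    positive = occupancy >= 1
    amplitudes = np.where(
        positive,
        rng.normal(params.pos_mean, params.pos_sd, size=params.n_droplets),
        rng.normal(params.neg_mean, params.neg_sd, size=params.n_droplets),
    )
    if params.rain_fraction > 0:
        n_rain = int(round(params.rain_fraction * params.n_droplets))
        idx = rng.choice(params.n_droplets, size=n_rain, replace=False)
        amplitudes[idx] = rng.uniform(params.neg_mean, params.pos_mean, size=n_rain)
    return DropletSet(well_id=well_id, channel=channel,
                      amplitudes=amplitudes, true_labels=positive)


def simulate_fluorometry(
    true_conc_ng_ul: float,
    cv: float,
    seed: int = 0,
    n_replicates: int = 4,
    model: str = "lognormal",
) -> FluorometryResult:
    """Simulate replicate fluorometric DNA concentration readings.

    Four replicates (two independent dilutions quantified twice) around
    ``true_conc_ng_ul`` with coefficient of variation ``cv``; the mean of
    the replicates is the concentration estimate.  The lognormal model is
    parameterised so the replicate expectation equals the true value
    (multiplicative error, concentrations strictly positive); a
    zero-truncated normal is available as an option.
    """
    if not true_conc_ng_ul > 0:
        raise ValueError("true_conc_ng_ul must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    if cv == 0:
        reps = np.full(n_replicates, true_conc_ng_ul)
    elif model == "lognormal":
        sigma2 = math.log1p(cv * cv)
        mu = math.log(true_conc_ng_ul) - sigma2 / 2.0
        reps = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_replicates)
    elif model == "truncnorm":
        reps = rng.normal(true_conc_ng_ul, cv * true_conc_ng_ul, size=n_replicates)
        while (reps <= 0).any():  # redraw the rare nonpositive readings
            bad = reps <= 0
            reps[bad] = rng.normal(true_conc_ng_ul, cv * true_conc_ng_ul,
                                   size=int(bad.sum()))
    else:
        raise ValueError("model must be 'lognormal' or 'truncnorm'")
    return FluorometryResult(
        replicates=tuple(float(r) for r in reps),
        mean=float(np.mean(reps)),
        sd=float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0,
    )


def simulate_mixture_copies(
    spec: MixtureSpec, assays: Mapping[str, SpeciesAssay]
) -> dict[str, float]:
    """True target copies per reaction for each component of a mixture.

    copies_s = mass_fraction_s × total mass (pg) / genome_size_1C_s (pg)
               × target_copies_per_haploid_s.

    Deterministic: this is the noise-free ground truth that droplet
    simulation and quantification are measured against.
    """
    copies: dict[str, float] = {}
    total_pg = spec.total_template_mass_ng * PG_PER_NG
    for species, frac in spec.components:
        if species not in assays:
            raise KeyError(f"no assay metadata for mixture component {species!r}")
        assay = assays[species]
        copies[species] = (
            frac * total_pg / assay.genome_size_1c_pg * assay.target_copies_per_haploid
        )
    return copies


def simulate_read_table(
    composition: Mapping[str, float],
    params: ReadSimParams,
    sample_id: str = "synthetic",
    kingdom: str = "Plantae",
) -> ReadTable:
    """Draw a distorted metabarcoding read table from a true composition.

    Expected read shares are proportional to abundance × bias, zeroed for
    dropped-out species and renormalised; ``total_reads`` reads are drawn
    multinomially and then re-labelled through the misattribution matrix.
    The returned table conserves ``total_reads`` exactly.
    """
    taxa = list(composition)
    ab = np.array([composition[t] for t in taxa], dtype=float)
    if (ab < 0).any() or not ab.any():
        raise ValueError("abundances must be >= 0 and not all zero")
    rng = np.random.default_rng(params.seed)

    weights = ab * np.array([params.bias.get(t, 1.0) for t in taxa])
    dropped = rng.random(len(taxa)) < np.array(
        [params.dropout.get(t, 0.0) for t in taxa]
    )
    weights[dropped] = 0.0
    if not weights.any():
        raise ValueError("all species dropped out; no reads to assign")
    origin_counts = rng.multinomial(params.total_reads, weights / weights.sum())

    if params.misattribution is None:
        out_taxa = taxa
        out_counts = origin_counts
    else:
        m = params.misattribution
        missing = set(taxa) - set(m.index)
        if missing:
            raise ValueError(f"misattribution matrix lacks rows for {sorted(missing)}")
        out_taxa = list(m.columns)
        out_counts = np.zeros(len(out_taxa), dtype=int)
        for taxon, count in zip(taxa, origin_counts):
            if count:
                out_counts += rng.multinomial(count, m.loc[taxon].to_numpy())

    df = pd.DataFrame({
        "taxon": out_taxa,
        "kingdom": kingdom,
        "reads": out_counts.astype(int),
    })
    return ReadTable(sample_id=sample_id, data=df)


def neighbour_misattribution(
    taxa: Sequence[str],
    neighbours: Mapping[str, Sequence[str]],
    leak: float = 0.02,
) -> pd.DataFrame:
    """Identity misattribution matrix with a leak to declared neighbours.

    Each taxon keeps 1 − leak of its reads; the leak is split evenly over
    its listed neighbours (phylogenetically adjacent taxa that short,
    slightly erroneous reads get attributed to).  Neighbours absent from
    ``taxa`` are added as extra columns/rows.
    """
    if not 0 <= leak < 1:
        raise ValueError("leak must lie in [0, 1)")
    all_taxa = list(dict.fromkeys(list(taxa) + [n for v in neighbours.values() for n in v]))
    m = pd.DataFrame(0.0, index=all_taxa, columns=all_taxa)
    for t in all_taxa:
        nbrs = [n for n in neighbours.get(t, []) if n != t]
        if nbrs:
            m.loc[t, t] = 1.0 - leak
            for n in nbrs:
                m.loc[t, n] = leak / len(nbrs)
        else:
            m.loc[t, t] = 1.0
    return m
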