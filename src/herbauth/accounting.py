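"""DNA accounting: a ddPCR purity screen for single-ingredient samples.

The screen asks whether all of a sample's DNA mass can be accounted for
by the declared species.  The fluorometrically measured DNA mass of the
template is converted into the number of target copies one would expect
if 100% of that mass belonged to the declared species,

    expected = mass_pg / genome_size_1C_pg × target_copies_per_haploid,

where ``genome_size_1C_pg`` is the haploid (1C) genome mass in picograms
and ``target_copies_per_haploid`` the number of assay target sites per
haploid genome.  The ddPCR-measured copy number is then compared against
an interval around this expectation; a measurement below the interval
means part of the DNA belongs to something else — dilution of the
declared ingredient by foreign material (or heavily degraded DNA).

The interval propagates fluorometric uncertainty linearly: expected
copies evaluated at mass mean ± k·sd, with the sd taken from the four
replicate fluorometer readings and k defaulting to 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .poisson import CopyEstimate

__all__ = [
    "SpeciesAssay",
    "ExpectedRange",
    "AccountingResult",
    "expected_copies",
    "expected_range",
    "account",
    "load_assays",
]

CLASS_LABELS = frozenset({"ingredient", "adulterant", "contaminant", "noise"})

PG_PER_NG = 1000.0


@dataclass(frozen=True)
class SpeciesAssay:
    """Per-species constants of a ddPCR assay.

    genome_size_1c_pg: haploid (1C) genome mass in picograms.
    ploidy: somatic ploidy level (2 for a diploid); only used when copy
        numbers are expressed per cell rather than per haploid genome.
    target_copies_per_haploid: copies of the assay target per haploid
        genome (single-copy nuclear targets are 1).
    class_label: role of the species in the authentication scheme.
    """

    species: str
    genome_size_1c_pg: float
    ploidy: int = 2
    target_copies_per_haploid: int = 1
    class_label: str = "contaminant"

    def __post_init__(self) -> None:
        if not self.genome_size_1c_pg > 0:
            raise ValueError("genome_size_1c_pg must be positive")
        if self.ploidy < 1 or self.target_copies_per_haploid < 1:
            raise ValueError("ploidy and target copies must be >= 1")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {sorted(CLASS_LABELS)}")


@dataclass(frozen=True)
class ExpectedRange:
    expected: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.expected <= self.high):
            raise ValueError("range must satisfy low <= expected <= high")


@dataclass(frozen=True)
class AccountingResult:
    """Outcome of the purity screen for one sample × assay."""

    expected_copies: float
    expected_low: float
    expected_high: float
    measured_copies: float
    ratio: float
    flag: str  # below | within | above


def expected_copies(template_mass_ng: float, assay: SpeciesAssay) -> float:
    """Target copies expected if the whole template mass is this species."""
    if not template_mass_ng > 0 or not math.isfinite(template_mass_ng):
        raise ValueError("template_mass_ng must be positive and finite")
    return (
        template_mass_ng * PG_PER_NG / assay.genome_size_1c_pg
    ) * assay.target_copies_per_haploid


def expected_range(
    template_mass_mean_ng: float,
    template_mass_sd_ng: float,
    assay: SpeciesAssay,
    k: float = 2.0,
) -> ExpectedRange:
    """Expected-copy interval from mass mean ± k·sd (linear propagation)."""
    if template_mass_sd_ng < 0:
        raise ValueError("template_mass_sd_ng must be >= 0")
    if k < 0:
        raise ValueError("coverage multiplier k must be >= 0")
    center = expected_copies(template_mass_mean_ng, assay)
    lo_mass = template_mass_mean_ng - k * template_mass_sd_ng
    hi_mass = template_mass_mean_ng + k * template_mass_sd_ng
    low = expected_copies(lo_mass, assay) if lo_mass > 0 else 0.0
    high = expected_copies(hi_mass, assay)
    return ExpectedRange(expected=center, low=low, high=high)


def account(measured: "CopyEstimate", rng: ExpectedRange) -> AccountingResult:
    """Flag a measured copy number as below / within / above expectation.

    ``measured.copies_per_reaction`` and ``rng`` must be on the same
    scale (both in target copies of the same assay, so any per-haploid
    target multiplicity cancels between the two sides).
    """
    m = measured.copies_per_reaction
    if m < rng.low:
        flag = "below"
    elif m > rng.high:
        flag = "above"
    else:
        flag = "within"
    return AccountingResult(
        expected_copies=rng.expected,
        expected_low=rng.low,
        expected_high=rng.high,
        measured_copies=m,
        ratio=m / rng.expected if rng.expected > 0 else math.nan,
        flag=flag,
    )


def load_assays(path) -> dict[str, SpeciesAssay]:
    """Load a species metadata TSV into a name-keyed assay map.

    Columns: species, genome_size_1c_pg, ploidy, target_copies_per_haploid,
    class_label.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "genome_size_1c_pg", "ploidy", "target_copies_per_haploid", "class_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    assays = {}
    for row in df.itertuples(index=False):
        assays[row.species] = SpeciesAssay(
            species=row.species,
            genome_size_1c_pg=float(row.genome_size_1c_pg),
            ploidy=int(row.ploidy),
            target_copies_per_haploid=int(row.target_copies_per_haploid),
            class_label=str(row.class_label),
        )
    return assays
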