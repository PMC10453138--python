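"""Copy-percentage estimation of a non-declared species in a declared matrix.

ddPCR measures copies of a *target sequence*; species differ in how many
target copies a genome carries, so raw copies are first corrected to
genome equivalents,

    GE = copies_per_reaction / target_copies_per_haploid,

(ploidy enters only when a per-cell convention is wanted: per-cell
equivalents divide additionally by ploidy).  The copy percentage of the
adulterant is then

    copy% = 100 · GE_adulterant / (GE_adulterant + GE_ingredient),

which is scale-invariant in the two copy measurements.  Converting GE to
DNA mass through each species' 1C genome size gives an optional mass
percentage comparable with gravimetric mixtures.

Adulterant measurements supported by fewer positive droplets than a
configurable floor (default 3) are reported as trace / not quantifiable
rather than as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .accounting import SpeciesAssay
from .poisson import CopyEstimate

__all__ = ["CopyFraction", "copy_fraction", "mass_fraction"]


@dataclass(frozen=True)
class CopyFraction:
    """Copy-number share of an adulterant relative to the declared ingredient.

    ``copy_pct`` is None when the result is not quantifiable (flags say
    why: ``not_detected`` for zero copies on both assays, or
    ``trace_not_quantifiable`` below the positive-droplet floor).
    """

    adulterant: str
    ingredient: str
    copy_pct: float | None
    ge_adulterant: float
    ge_ingredient: float
    mass_pct: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.copy_pct is not None and not 0.0 <= self.copy_pct <= 100.0:
            raise ValueError("copy_pct must lie in [0, 100]")


def _genome_equivalents(est: CopyEstimate, assay: SpeciesAssay, units: str) -> float:
    ge = est.copies_per_reaction / assay.target_copies_per_haploid
    if units == "per_cell":
        ge /= assay.ploidy
    elif units != "per_haploid":
        raise ValueError("units must be 'per_haploid' or 'per_cell'")
    return ge


def copy_fraction(
    adulterant_est: CopyEstimate,
    ingredient_est: CopyEstimate,
    adulterant_assay: SpeciesAssay,
    ingredient_assay: SpeciesAssay,
    units: str = "per_haploid",
    min_positive_droplets: int = 3,
) -> CopyFraction:
    """Copy percentage of the non-declared species in a two-species extract.

    Both estimates must come from the same DNA extract.  ``units``
    selects the normalisation convention: genome equivalents per haploid
    genome (default; ploidy-independent) or per cell (divides by
    ploidy).  The convention cancels in copy% only when both species
    share a ploidy level, hence the explicit switch.
    """
    ge_a = _genome_equivalents(adulterant_est, adulterant_assay, units)
    ge_i = _genome_equivalents(ingredient_est, ingredient_assay, units)
    flags: set[str] = set()
    if ge_a == 0.0 and ge_i == 0.0:
        return CopyFraction(
            adulterant=adulterant_assay.species, ingredient=ingredient_assay.species,
            copy_pct=None, ge_adulterant=0.0, ge_ingredient=0.0,
            flags=frozenset({"not_detected"}),
        )
    pct: float | None
    if adulterant_est.n_positive == 0:
        flags.add("adulterant_not_detected")
        pct = 0.0
    elif adulterant_est.n_positive < min_positive_droplets:
        flags.add("trace_not_quantifiable")
        pct = None
    else:
        pct = 100.0 * ge_a / (ge_a + ge_i)
    return CopyFraction(
        adulterant=adulterant_assay.species,
        ingredient=ingredient_assay.species,
        copy_pct=pct,
        ge_adulterant=ge_a,
        ge_ingredient=ge_i,
        flags=frozenset(flags),
    )


def mass_fraction(
    cf: CopyFraction,
    adulterant_assay: SpeciesAssay,
    ingredient_assay: SpeciesAssay,
) -> float:
    """Convert a copy fraction to a DNA-mass percentage.

    Mass of each component is GE × 1C genome mass; the result is the
    adulterant's share of the combined DNA mass, directly comparable
    with gravimetric (m/m) mixture design when DNA content per unit
    tissue mass is similar between the species.
    """
    if cf.copy_pct is None:
        raise ValueError(f"copy fraction not quantifiable ({set(cf.flags)})")
    m_a = cf.ge_adulterant * adulterant_assay.genome_size_1c_pg
    m_i = cf.ge_ingredient * ingredient_assay.genome_size_1c_pg
    if m_a + m_i == 0.0:
        raise ValueError("zero total DNA mass")
    return 100.0 * m_a / (m_a + m_i)
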