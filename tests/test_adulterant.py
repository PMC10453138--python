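"""Adulterant copy-percentage and mass-percentage estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbauth import (
    DropletCall,
    DropletSimParams,
    MixtureSpec,
    SpeciesAssay,
    call_droplets,
    copy_fraction,
    estimate_lambda,
    mass_fraction,
    simulate_droplets,
    simulate_mixture_copies,
)
from herbauth.adulterant import CopyFraction


def _estimate_for_copies(copies, n_total=1_000_000):
    """Estimate whose copies_per_reaction is (essentially) the given count."""
    lam = copies / n_total
    n_neg = int(round(n_total * np.exp(-lam)))
    call = DropletCall(well_id="w", channel=1, n_total=n_total,
                       n_positive=n_total - n_neg, n_negative=n_neg,
                       threshold=None, n_rain_reassigned=0)
    return estimate_lambda(call)


@pytest.fixture(scope="module")
def unit_pair():
    return (SpeciesAssay("olive", genome_size_1c_pg=1.0, class_label="adulterant"),
            SpeciesAssay("oregano", genome_size_1c_pg=1.0, class_label="ingredient"))


class TestCopyFraction:
    def test_one_percent(self, unit_pair):
        olive, oregano = unit_pair
        cf = copy_fraction(_estimate_for_copies(10), _estimate_for_copies(990),
                           olive, oregano)
        assert cf.copy_pct == pytest.approx(1.0, abs=0.01)

    def test_target_copy_correction(self):
        # 200 copies of a 2-copy target vs 900 of a single-copy target:
        # genome equivalents 100 vs 900, i.e. 10%
        adult = SpeciesAssay("a", genome_size_1c_pg=1.0,
                             target_copies_per_haploid=2,
                             class_label="adulterant")
        ingr = SpeciesAssay("i", genome_size_1c_pg=1.0,
                            class_label="ingredient")
        cf = copy_fraction(_estimate_for_copies(200), _estimate_for_copies(900),
                           adult, ingr)
        assert cf.copy_pct == pytest.approx(10.0, abs=0.05)

    def test_per_cell_units_divide_by_ploidy(self):
        adult = SpeciesAssay("a", genome_size_1c_pg=1.0, ploidy=4,
                             class_label="adulterant")
        ingr = SpeciesAssay("i", genome_size_1c_pg=1.0, ploidy=2,
                            class_label="ingredient")
        per_hap = copy_fraction(_estimate_for_copies(400),
                                _estimate_for_copies(600), adult, ingr)
        per_cell = copy_fraction(_estimate_for_copies(400),
                                 _estimate_for_copies(600), adult, ingr,
                                 units="per_cell")
        assert per_cell.ge_adulterant == pytest.approx(per_hap.ge_adulterant / 4)
        assert per_cell.copy_pct < per_hap.copy_pct

    def test_both_zero_not_detected(self, unit_pair):
        olive, oregano = unit_pair
        zero = _estimate_for_copies(0)
        cf = copy_fraction(zero, zero, olive, oregano)
        assert cf.copy_pct is None
        assert "not_detected" in cf.flags

    def test_trace_below_lod_not_quantified(self, unit_pair):
        olive, oregano = unit_pair
        cf = copy_fraction(_estimate_for_copies(2), _estimate_for_copies(10_000),
                           olive, oregano)
        assert cf.copy_pct is None
        assert "trace_not_quantifiable" in cf.flags

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=1000.0))
    def test_scale_invariance(self, scale):
        olive = SpeciesAssay("olive", genome_size_1c_pg=1.0,
                             class_label="adulterant")
        oregano = SpeciesAssay("oregano", genome_size_1c_pg=1.0,
                               class_label="ingredient")
        base = copy_fraction(_estimate_for_copies(50), _estimate_for_copies(500),
                             olive, oregano)
        scaled = copy_fraction(_estimate_for_copies(50 * scale),
                               _estimate_for_copies(500 * scale),
                               olive, oregano)
        assert scaled.copy_pct == pytest.approx(base.copy_pct, rel=1e-3)

    def test_monotone_in_adulterant_copies(self, unit_pair):
        olive, oregano = unit_pair
        ingr = _estimate_for_copies(1000)
        pcts = [copy_fraction(_estimate_for_copies(c), ingr, olive, oregano).copy_pct
                for c in (10, 50, 200, 800)]
        assert all(b > a for a, b in zip(pcts, pcts[1:]))


class TestMassFraction:
    def test_equal_genomes_mass_equals_copy(self, unit_pair):
        olive, oregano = unit_pair
        cf = copy_fraction(_estimate_for_copies(100), _estimate_for_copies(900),
                           olive, oregano)
        assert mass_fraction(cf, olive, oregano) == pytest.approx(cf.copy_pct,
                                                                  rel=1e-6)

    def test_double_genome_hand_oracle(self):
        # adulterant genome twice the matrix genome at copy% 33.33 -> 50% mass
        adult = SpeciesAssay("a", genome_size_1c_pg=2.0, class_label="adulterant")
        ingr = SpeciesAssay("i", genome_size_1c_pg=1.0, class_label="ingredient")
        cf = CopyFraction(adulterant="a", ingredient="i",
                          copy_pct=100 / 3, ge_adulterant=100.0,
                          ge_ingredient=200.0)
        assert mass_fraction(cf, adult, ingr) == pytest.approx(50.0, abs=1e-6)

    def test_round_trip_recovers_mass_fraction(self):
        # noise-free: mixture -> copies -> copy fraction -> mass fraction
        # is the identity on the input mass fraction
        assays = {
            "olive": SpeciesAssay("olive", genome_size_1c_pg=1.42,
                                  class_label="adulterant"),
            "oregano": SpeciesAssay("oregano", genome_size_1c_pg=0.96,
                                    class_label="ingredient"),
        }
        for f in (0.01, 0.05, 0.30):
            spec = MixtureSpec(components=(("olive", f), ("oregano", 1 - f)))
            copies = simulate_mixture_copies(spec, assays)
            cf = CopyFraction(
                adulterant="olive", ingredient="oregano",
                copy_pct=100 * copies["olive"] / (copies["olive"] + copies["oregano"]),
                ge_adulterant=copies["olive"], ge_ingredient=copies["oregano"])
            assert mass_fraction(cf, assays["olive"], assays["oregano"]) == \
                pytest.approx(100 * f, rel=1e-9)

    def test_unquantifiable_fraction_rejected(self, unit_pair):
        olive, oregano = unit_pair
        cf = CopyFraction(adulterant="olive", ingredient="oregano",
                          copy_pct=None, ge_adulterant=0.0, ge_ingredient=0.0,
                          flags=frozenset({"not_detected"}))
        with pytest.raises(ValueError):
            mass_fraction(cf, olive, oregano)


class TestEndToEndMixtureRecovery:
    def test_five_percent_olive_mixture(self, equal_assays):
        # full chain on a 5% (m/m) mixture with equal genome sizes: every
        # replicate's copy% must land in the declared recovery band
        spec = MixtureSpec(components=(("olive", 0.05), ("oregano", 0.95)))
        true_copies = simulate_mixture_copies(spec, equal_assays)
        rng = np.random.default_rng(99)
        pcts = []
        for _ in range(25):
            ests = {}
            for sp in ("olive", "oregano"):
                ds = simulate_droplets(DropletSimParams(
                    lambda_true=true_copies[sp] / 20_000, n_droplets=20_000,
                    seed=int(rng.integers(0, 2**31 - 1))))
                ests[sp] = estimate_lambda(call_droplets(ds))
            cf = copy_fraction(ests["olive"], ests["oregano"],
                               equal_assays["olive"], equal_assays["oregano"])
            pcts.append(cf.copy_pct)
        assert all(3.5 <= p <= 6.5 for p in pcts)
        assert np.mean(pcts) == pytest.approx(5.0, abs=0.5)
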