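"""Generators: Poisson droplet partitioning, fluorometry noise, mixtures,
biased read tables."""

import math

import numpy as np
import pandas as pd
import pytest

from herbauth import (
    DropletSimParams,
    MixtureSpec,
    ReadSimParams,
    SpeciesAssay,
    neighbour_misattribution,
    simulate_droplets,
    simulate_fluorometry,
    simulate_mixture_copies,
    simulate_read_table,
)


class TestSimulateDroplets:
    def test_zero_lambda_all_negative(self):
        ds = simulate_droplets(DropletSimParams(lambda_true=0.0, n_droplets=5000))
        assert not ds.true_labels.any()

    def test_negative_fraction_matches_poisson_law(self):
        # P(occupancy = 0) = e^{-lambda}; at lambda = ln 2 half the droplets
        # are empty, within binomial fluctuation
        n = 100_000
        lam = math.log(2)
        ds = simulate_droplets(DropletSimParams(lambda_true=lam, n_droplets=n, seed=5))
        frac_neg = 1.0 - ds.true_labels.mean()
        sd = math.sqrt(0.5 * 0.5 / n)
        assert abs(frac_neg - 0.5) < 5 * sd

    @pytest.mark.parametrize("lam", [0.01, 0.3, 1.2])
    def test_negative_fraction_general_lambda(self, lam):
        n = 100_000
        ds = simulate_droplets(DropletSimParams(lambda_true=lam, n_droplets=n, seed=9))
        p = math.exp(-lam)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs((1.0 - ds.true_labels.mean()) - p) < 5 * sd

    def test_bit_reproducible_under_seed(self):
        params = DropletSimParams(lambda_true=0.1, n_droplets=20000, seed=77)
        a = simulate_droplets(params)
        b = simulate_droplets(params)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        np.testing.assert_array_equal(a.true_labels, b.true_labels)

    def test_rain_droplets_keep_ground_truth(self):
        params = DropletSimParams(lambda_true=0.5, n_droplets=10000,
                                  rain_fraction=0.05, seed=2)
        ds = simulate_droplets(params)
        # ground truth is occupancy-based: its positive share must match the
        # Poisson law even though some amplitudes sit mid-range
        p_pos = 1 - math.exp(-0.5)
        assert abs(ds.true_labels.mean() - p_pos) < 5 * math.sqrt(p_pos * (1 - p_pos) / 10000)
        mid = (ds.amplitudes > 3000) & (ds.amplitudes < 7000)
        assert mid.sum() > 0

    @pytest.mark.parametrize("kwargs", [
        {"lambda_true": -0.1},
        {"lambda_true": math.nan},
        {"lambda_true": 0.1, "n_droplets": 0},
        {"lambda_true": 0.1, "neg_mean": 9000.0},  # pos_mean must exceed neg
        {"lambda_true": 0.1, "neg_sd": 0.0},
        {"lambda_true": 0.1, "rain_fraction": 1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DropletSimParams(**kwargs)


class TestSimulateFluorometry:
    def test_zero_cv_replicates_equal_truth(self):
        res = simulate_fluorometry(7.5, cv=0.0, seed=1)
        assert res.replicates == (7.5,) * 4
        assert res.mean == 7.5 and res.sd == 0.0

    def test_lognormal_model_is_unbiased(self):
        # Monte-Carlo check: mean of replicate means converges to the truth
        means = [simulate_fluorometry(10.0, cv=0.05, seed=s).mean
                 for s in range(10_000)]
        assert abs(np.mean(means) - 10.0) / 10.0 < 0.005

    def test_truncnorm_option_positive(self):
        res = simulate_fluorometry(0.2, cv=0.5, seed=3, model="truncnorm")
        assert all(r > 0 for r in res.replicates)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_fluorometry(0.0, cv=0.05)
        with pytest.raises(ValueError):
            simulate_fluorometry(10.0, cv=-0.01)


class TestSimulateMixtureCopies:
    def test_pure_sample_copies(self, equal_assays):
        # 18 ng = 18,000 pg at 1 pg/1C and one target per haploid genome
        spec = MixtureSpec(components=(("oregano", 1.0),),
                           total_template_mass_ng=18.0)
        copies = simulate_mixture_copies(spec, equal_assays)
        assert copies["oregano"] == pytest.approx(18_000.0)

    def test_equal_genomes_proportionality(self, equal_assays):
        spec = MixtureSpec(components=(("olive", 0.05), ("oregano", 0.95)))
        copies = simulate_mixture_copies(spec, equal_assays)
        total = sum(copies.values())
        assert copies["olive"] / total == pytest.approx(0.05)

    def test_unequal_genomes_hand_oracle(self):
        # 5% by mass with a 2 pg adulterant genome vs 1 pg matrix genome:
        # copy fraction = (0.05/2) / (0.05/2 + 0.95/1) = 2.5641%
        assays = {
            "olive": SpeciesAssay("olive", genome_size_1c_pg=2.0,
                                  class_label="adulterant"),
            "oregano": SpeciesAssay("oregano", genome_size_1c_pg=1.0,
                                    class_label="ingredient"),
        }
        spec = MixtureSpec(components=(("olive", 0.05), ("oregano", 0.95)))
        copies = simulate_mixture_copies(spec, assays)
        frac = copies["olive"] / (copies["olive"] + copies["oregano"])
        assert frac * 100 == pytest.approx(2.5641, abs=1e-3)

    def test_missing_assay_entry_raises(self, equal_assays):
        spec = MixtureSpec(components=(("sumac", 1.0),))
        with pytest.raises(KeyError):
            simulate_mixture_copies(spec, equal_assays)

    def test_mixture_spec_invariants(self):
        with pytest.raises(ValueError):
            MixtureSpec(components=(("a", 0.6), ("b", 0.6)))
        with pytest.raises(ValueError):
            MixtureSpec(components=(("a", 1.0),), total_template_mass_ng=0.0)


class TestSimulateReadTable:
    def test_unbiased_multinomial_shares(self):
        n = 1_000_000
        rt = simulate_read_table(
            {"a": 1.0, "b": 1.0},
            ReadSimParams(total_reads=n, seed=8),
        )
        counts = dict(zip(rt.data["taxon"], rt.data["reads"]))
        sd = math.sqrt(0.25 * n)
        assert abs(counts["a"] - n / 2) < 5 * sd
        assert counts["a"] + counts["b"] == n

    def test_total_reads_conserved_under_misattribution(self):
        m = neighbour_misattribution(["a", "b"], {"a": ["c"]}, leak=0.1)
        rt = simulate_read_table(
            {"a": 3.0, "b": 1.0},
            ReadSimParams(total_reads=5000, misattribution=m, seed=4),
        )
        assert rt.total_reads == 5000
        assert set(rt.data["taxon"]) == {"a", "b", "c"}

    def test_dropout_silences_species(self):
        rt = simulate_read_table(
            {"sumac": 10.0, "oregano": 1.0},
            ReadSimParams(total_reads=10_000, dropout={"sumac": 1.0}, seed=6),
        )
        counts = dict(zip(rt.data["taxon"], rt.data["reads"]))
        assert counts["sumac"] == 0
        assert counts["oregano"] == 10_000

    def test_bias_inflates_minor_component(self):
        # a 30x over-amplified 1% weed must dominate its true share
        rt = simulate_read_table(
            {"weed": 0.01, "oregano": 0.99},
            ReadSimParams(total_reads=100_000, bias={"weed": 30.0}, seed=11),
        )
        counts = dict(zip(rt.data["taxon"], rt.data["reads"]))
        weed_pct = 100.0 * counts["weed"] / 100_000
        assert weed_pct > 15.0  # expected ~23%, far above the 1% truth

    def test_invalid_stochastic_matrix_rejected(self):
        bad = pd.DataFrame([[0.5, 0.4], [0.0, 1.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ReadSimParams(total_reads=100, misattribution=bad)

    def test_reproducible_under_seed(self):
        params = ReadSimParams(total_reads=1000, bias={"a": 2.0}, seed=3)
        r1 = simulate_read_table({"a": 1.0, "b": 2.0}, params)
        r2 = simulate_read_table({"a": 1.0, "b": 2.0}, params)
        pd.testing.assert_frame_equal(r1.data, r2.data)
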