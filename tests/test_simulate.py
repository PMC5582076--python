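"""Simulator: DH genotype structure, Haldane map, architecture, trials, masking."""

import numpy as np
import pandas as pd
import pytest

from dhgs import (
    SimConfig,
    assign_genetic_architecture,
    gxe_sd_for_between_year_correlation,
    mask_genotypes,
    simulate_dh_genotypes,
    simulate_population,
    simulate_trials,
)
from dhgs.simulate import haldane_recombination_fraction, line_means


class TestDHGenotypes:
    def test_all_codes_homozygous(self, tiny_genotypes):
        assert set(np.unique(tiny_genotypes.values)) <= {-1.0, 1.0}

    def test_markers_ordered_by_chromosome_then_position(self):
        cfg = SimConfig(n_lines=5, chromosomes=(50.0, 30.0), markers_per_chromosome=4, seed=1)
        pop = simulate_dh_genotypes(cfg)
        gm = pop.genetic_map
        assert list(gm["chromosome"]) == sorted(gm["chromosome"])
        for _, sub in gm.groupby("chromosome"):
            assert list(sub["cM"]) == sorted(sub["cM"])

    def test_identical_map_position_gives_identical_columns(self):
        cfg = SimConfig(
            n_lines=200,
            chromosomes=(50.0,),
            markers_per_chromosome=3,
            marker_positions=((0.0, 20.0, 20.0),),
            seed=3,
        )
        V = simulate_dh_genotypes(cfg).genotypes.values
        np.testing.assert_array_equal(V[:, 1], V[:, 2])

    def test_haldane_recombination_fraction_10cm(self):
        # closed form: 0.5 (1 - e^(-0.2)) = 0.0906
        cfg = SimConfig(
            n_lines=5000,
            chromosomes=(10.0,),
            markers_per_chromosome=2,
            seed=11,
        )
        V = simulate_dh_genotypes(cfg).genotypes.values
        recomb = np.mean(V[:, 0] != V[:, 1])
        assert abs(recomb - 0.0906) < 0.01

    def test_allele_frequency_near_half(self):
        cfg = SimConfig(n_lines=2000, chromosomes=(100.0,) * 2, markers_per_chromosome=20, seed=5)
        V = simulate_dh_genotypes(cfg).genotypes.values
        freqs = (V.mean(axis=0) + 1) / 2
        assert np.all(np.abs(freqs - 0.5) < 4 * 0.5 / np.sqrt(2000))

    def test_ld_decays_with_map_distance(self):
        cfg = SimConfig(n_lines=3000, chromosomes=(100.0,), markers_per_chromosome=11, seed=9)
        V = simulate_dh_genotypes(cfg).genotypes.values
        corr_with_first = [abs(np.corrcoef(V[:, 0], V[:, j])[0, 1]) for j in (1, 4, 10)]
        assert corr_with_first[0] > corr_with_first[1] > corr_with_first[2]

    def test_zero_length_chromosome_with_markers_errors(self):
        cfg = SimConfig(n_lines=5, chromosomes=(0.0,), markers_per_chromosome=3, seed=1)
        with pytest.raises(ValueError, match="non-positive map length"):
            simulate_dh_genotypes(cfg)


class TestArchitecture:
    def test_no_qtl_means_zero_genetic_values(self):
        cfg = SimConfig(n_lines=30, chromosomes=(50.0,), markers_per_chromosome=10, n_qtl=0, seed=2)
        pop = assign_genetic_architecture(simulate_dh_genotypes(cfg), cfg)
        assert np.all(pop.true_genetic_values == 0)

    def test_too_many_qtl_errors(self):
        cfg = SimConfig(n_lines=10, chromosomes=(50.0,), markers_per_chromosome=10, n_qtl=11, seed=2)
        with pytest.raises(ValueError, match="exceeds marker count"):
            assign_genetic_architecture(simulate_dh_genotypes(cfg), cfg)

    def test_realized_heritability_matches_target(self):
        # additive variance over total line-mean phenotypic variance ~ h2
        cfg = SimConfig(
            n_lines=2000,
            chromosomes=(100.0,) * 5,
            markers_per_chromosome=40,
            n_qtl=100,
            h2=0.5,
            gxe_sd=0.0,
            seed=13,
        )
        pop, trials, _ = simulate_population(cfg)
        lm = line_means(trials)
        y1 = lm[lm["year"] == 1].set_index("line")["yield"]
        ratio = pop.true_additive_values.var() / y1.var()
        assert abs(ratio - 0.5) < 0.05

    def test_epistatic_variance_fraction(self):
        # half the genetic variance epistatic: components match within 10%
        ratios = []
        for seed in range(20):
            cfg = SimConfig(
                n_lines=300,
                chromosomes=(100.0,) * 3,
                markers_per_chromosome=30,
                n_qtl=40,
                epistasis_fraction=0.5,
                h2=0.4,
                seed=seed,
            )
            pop = assign_genetic_architecture(simulate_dh_genotypes(cfg), cfg)
            epi = pop.true_genetic_values - pop.true_additive_values
            ratios.append(epi.var() / pop.true_additive_values.var())
        assert abs(np.mean(ratios) - 1.0) < 0.1


class TestTrials:
    def test_noise_free_years_identical(self):
        cfg = SimConfig(
            n_lines=50,
            chromosomes=(80.0,) * 2,
            markers_per_chromosome=20,
            n_qtl=30,
            gxe_sd=0.0,
            resid_sd=0.0,
            seed=4,
        )
        pop, trials, _ = simulate_population(cfg)
        lm = line_means(trials).pivot(index="line", columns="year", values="yield")
        assert np.corrcoef(lm[1], lm[2])[0, 1] == pytest.approx(1.0)

    def test_year_means_match_defaults(self):
        cfg = SimConfig(chromosomes=(100.0,) * 5, markers_per_chromosome=40, n_qtl=150, seed=21)
        _, trials, _ = simulate_population(cfg)
        for year, target in ((1, 1579.73), (2, 2228.03)):
            sub = trials[trials["year"] == year]["yield"]
            sem = sub.std() / np.sqrt(len(sub))
            assert abs(sub.mean() - target) < 2 * sem

    def test_between_year_correlation_near_0_42(self):
        rhos = []
        for seed in range(4):
            cfg = SimConfig(
                n_lines=500, chromosomes=(120.0,) * 8, markers_per_chromosome=40, seed=seed
            )
            _, trials, _ = simulate_population(cfg)
            lm = line_means(trials).pivot(index="line", columns="year", values="yield")
            rhos.append(np.corrcoef(lm[1], lm[2])[0, 1])
        assert abs(np.mean(rhos) - 0.42) < 0.05

    def test_gxe_tuning_closed_form_consistency(self):
        sd = gxe_sd_for_between_year_correlation(0.417, h2=0.5, resid_sd=250.0, n_reps=2)
        var_g = 0.5 * 250.0**2 / 2 / 0.5
        rho = var_g / (var_g + sd**2 + 250.0**2 / 2)
        assert rho == pytest.approx(0.417)

    def test_rust_scored_year2_only_and_bounded(self, small_pop):
        _, _, trials, _ = small_pop
        y1 = trials[trials["year"] == 1]
        y2 = trials[trials["year"] == 2]
        assert y1["RS5"].isna().all()
        assert y2["RS5"].between(0, 9).all()
        assert y2["RI5"].between(0, 100).all()

    def test_heading_date_correlates_with_genetic_value(self):
        cfg = SimConfig(
            n_lines=800,
            chromosomes=(100.0,) * 4,
            markers_per_chromosome=30,
            n_qtl=80,
            hd_genetic_cor=0.5,
            seed=31,
        )
        pop, trials, _ = simulate_population(cfg)
        hd = trials[trials["year"] == 1].groupby("line", sort=False)["HD"].mean()
        r = np.corrcoef(hd.to_numpy(), pop.true_genetic_values)[0, 1]
        assert abs(r - 0.5) < 0.1

    def test_zero_reps_errors(self):
        with pytest.raises(ValueError, match="n_reps"):
            SimConfig(n_reps=0)


class TestMasking:
    def test_full_call_rate_is_identity(self, tiny_genotypes):
        cfg = SimConfig(n_lines=5, call_rate_mean=1.0, call_rate_spread=0.0, seed=1)
        out = mask_genotypes(tiny_genotypes, cfg)
        np.testing.assert_array_equal(out.values, tiny_genotypes.values)

    def test_masking_deterministic_under_seed(self, tiny_genotypes):
        cfg = SimConfig(n_lines=5, call_rate_mean=0.6, seed=42)
        a = mask_genotypes(tiny_genotypes, cfg)
        b = mask_genotypes(tiny_genotypes, cfg)
        np.testing.assert_array_equal(np.isnan(a.values), np.isnan(b.values))

    def test_realized_call_rates_binomial_consistent(self):
        cfg = SimConfig(
            n_lines=1000,
            chromosomes=(100.0,),
            markers_per_chromosome=50,
            call_rate_mean=0.6,
            seed=17,
        )
        pop = simulate_dh_genotypes(cfg)
        masked = mask_genotypes(pop.genotypes, cfg)
        realized = masked.call_rates()
        # 99% binomial band around each marker's drawn rate is unknown; the
        # realized rates must at least average near the configured mean
        assert abs(realized.mean() - 0.6) < 0.03
        # and no realized rate can deviate from [0,1]
        assert realized.min() >= 0 and realized.max() <= 1

    def test_mean_call_rate_distribution(self):
        cfg = SimConfig(
            n_lines=400,
            chromosomes=(100.0,) * 2,
            markers_per_chromosome=100,
            call_rate_mean=0.6,
            call_rate_spread=0.15,
            seed=19,
        )
        pop = simulate_dh_genotypes(cfg)
        rates = mask_genotypes(pop.genotypes, cfg).call_rates()
        assert abs(rates.mean() - 0.6) < 0.03
        assert 0.08 < rates.std() < 0.25


def test_simulate_population_writes_round_trippable_files(tmp_path, small_pop):
    from dhgs.genotypes import read_genotype_tsv
    from dhgs.simulate import write_population

    _, pop, trials, masked = small_pop
    write_population(pop, trials, masked, tmp_path)
    M = read_genotype_tsv(tmp_path / "genotypes.tsv")
    assert M.n_lines == pop.genotypes.n_lines
    np.testing.assert_allclose(M.values, masked.values, atol=1e-5)
    truth = pd.read_csv(tmp_path / "truth.csv")
    assert len(truth) == pop.genotypes.n_lines
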