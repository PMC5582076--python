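"""Filtering, imputation, and relationship matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhgs import (
    MarkerMatrix,
    SimConfig,
    filter_by_call_rate,
    gaussian_kernel,
    impute_em,
    impute_mean,
    mask_genotypes,
    vanraden_grm,
)
from dhgs.genotypes import allele_frequencies

from conftest import random_marker_matrix


def mm(values, line_ids=None, marker_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return MarkerMatrix(
        line_ids or [f"L{i}" for i in range(n)],
        marker_ids or [f"M{j}" for j in range(m)],
        values,
    )


class TestCallRateFilter:
    def test_strict_threshold_comparison(self):
        nan = np.nan
        # call rates 1.0, 0.8, 0.5, 0.2 over 5 lines... build per column
        cols = {
            1.0: [1, 1, 1, 1, 1],
            0.8: [1, 1, 1, 1, nan],
            0.6: [1, 1, 1, nan, nan],
            0.2: [1, nan, nan, nan, nan],
        }
        M = mm(np.column_stack(list(cols.values())))
        out = filter_by_call_rate(M, 0.6)
        assert out.n_markers == 2  # 1.0 and 0.8 survive; exactly 0.6 excluded

    def test_min_rate_zero_keeps_any_observed(self):
        M = mm([[1, np.nan], [np.nan, np.nan]])
        out = filter_by_call_rate(M, 0.0)
        assert out.marker_ids == ["M0"]

    def test_invalid_rate_errors(self, tiny_genotypes):
        with pytest.raises(ValueError):
            filter_by_call_rate(tiny_genotypes, 1.5)

    def test_retained_count_non_increasing_in_threshold(self, tiny_genotypes):
        cfg = SimConfig(n_lines=5, call_rate_mean=0.6, seed=3)
        masked = mask_genotypes(tiny_genotypes, cfg)
        counts = [
            filter_by_call_rate(masked, r).n_markers for r in (0.25, 0.4, 0.5, 0.6, 0.75)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMeanImputation:
    def test_symmetric_column_imputes_zero(self):
        M = mm([[-1], [1], [np.nan]])
        assert impute_mean(M).values[2, 0] == pytest.approx(0.0)

    def test_monomorphic_column_imputes_code(self):
        M = mm([[1], [1], [1], [np.nan]])
        assert impute_mean(M).values[3, 0] == pytest.approx(1.0)

    def test_complete_matrix_unchanged(self, tiny_genotypes):
        out = impute_mean(tiny_genotypes)
        np.testing.assert_array_equal(out.values, tiny_genotypes.values)

    def test_all_missing_marker_errors(self):
        M = mm([[1, np.nan], [1, np.nan]])
        with pytest.raises(ValueError, match="M1"):
            impute_mean(M)

    def test_preserves_observed_allele_frequency(self, tiny_genotypes):
        cfg = SimConfig(n_lines=5, call_rate_mean=0.7, seed=9)
        masked = mask_genotypes(tiny_genotypes, cfg)
        filled = impute_mean(masked)
        obs_freq = (np.nanmean(masked.values, axis=0) + 1) / 2
        np.testing.assert_allclose(allele_frequencies(filled), obs_freq, atol=1e-12)


class TestEMImputation:
    def test_complete_matrix_identity_zero_iterations(self, tiny_genotypes):
        out, converged, n_iter = impute_em(tiny_genotypes)
        assert converged and n_iter == 0
        np.testing.assert_array_equal(out.values, tiny_genotypes.values)

    def test_duplicated_line_restored_from_twin(self):
        # perfect relatedness: a copy of line 0 with masked entries must be
        # restored to the twin's genotypes almost exactly (markers must
        # comfortably outnumber lines, as in GBS data)
        from dhgs import simulate_dh_genotypes

        cfg = SimConfig(n_lines=40, chromosomes=(100.0,) * 4, markers_per_chromosome=100, seed=7)
        base = simulate_dh_genotypes(cfg).genotypes
        rng = np.random.default_rng(5)
        V = np.vstack([base.values, base.values[0]])
        masked_cols = rng.choice(base.n_markers, 30, replace=False)
        V[-1, masked_cols] = np.nan
        M = MarkerMatrix(base.line_ids + ["twin"], list(base.marker_ids), V)
        out, _, _ = impute_em(M, tol=1e-6, max_iter=300)
        np.testing.assert_allclose(
            out.values[-1, masked_cols], base.values[0, masked_cols], atol=0.05
        )

    def test_em_beats_mean_imputation_rmse(self):
        cfg = SimConfig(
            n_lines=100,
            chromosomes=(120.0,) * 3,
            markers_per_chromosome=50,
            call_rate_mean=0.8,
            call_rate_spread=0.1,
            seed=23,
        )
        from dhgs import simulate_dh_genotypes

        pop = simulate_dh_genotypes(cfg)
        masked = mask_genotypes(pop.genotypes, cfg)
        miss = np.isnan(masked.values)
        truth = pop.genotypes.values
        em = impute_em(masked)[0].values
        mean = impute_mean(masked).values
        rmse_em = np.sqrt(np.mean((em[miss] - truth[miss]) ** 2))
        rmse_mean = np.sqrt(np.mean((mean[miss] - truth[miss]) ** 2))
        assert rmse_em < rmse_mean

    def test_single_line_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            impute_em(mm([[1.0, np.nan]]))


class TestVanRadenG:
    def test_brute_force_equivalence_random_matrices(self):
        # oracle: double-loop evaluation of Z Z' / (2 sum p(1-p))
        rng = np.random.default_rng(0)
        for _ in range(5):
            M = random_marker_matrix(rng, 5, 10)
            p = (M.values.mean(axis=0) + 1) / 2
            poly = (p > 0) & (p < 1)
            if not poly.any():
                continue
            Z = M.values[:, poly] - 2 * (p[poly] - 0.5)
            denom = float((2 * p[poly] * (1 - p[poly])).sum())
            expected = np.empty((5, 5))
            for j in range(5):
                for k in range(5):
                    expected[j, k] = float(Z[j] @ Z[k]) / denom
            G = vanraden_grm(M)
            np.testing.assert_allclose(G.values, expected, atol=1e-12)

    def test_all_half_frequency_diagonal(self):
        # m markers at p=0.5, a line scored +1 everywhere: diagonal = 2
        V = np.array([[1.0, 1.0, 1.0, 1.0], [-1, -1, -1, -1], [1, -1, 1, -1], [-1, 1, -1, 1]])
        G = vanraden_grm(mm(V))
        assert G.values[0, 0] == pytest.approx(2.0)

    def test_identical_lines_offdiagonal_equals_diagonal(self, tiny_genotypes):
        V = np.vstack([tiny_genotypes.values, tiny_genotypes.values[0]])
        M = MarkerMatrix(
            tiny_genotypes.line_ids + ["copy"], list(tiny_genotypes.marker_ids), V
        )
        G = vanraden_grm(M).values
        assert G[0, -1] == pytest.approx(G[0, 0])
        assert G[-1, -1] == pytest.approx(G[0, 0])

    def test_monomorphic_marker_leaves_g_unchanged(self, tiny_genotypes):
        G0 = vanraden_grm(tiny_genotypes).values
        V = np.column_stack([tiny_genotypes.values, np.ones(tiny_genotypes.n_lines)])
        M = MarkerMatrix(
            list(tiny_genotypes.line_ids), tiny_genotypes.marker_ids + ["mono"], V
        )
        np.testing.assert_allclose(vanraden_grm(M).values, G0, atol=1e-12)

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(mm(np.ones((3, 4))))

    def test_psd_to_tolerance(self, tiny_genotypes):
        eig = np.linalg.eigvalsh(vanraden_grm(tiny_genotypes).values)
        assert eig.min() > -1e-8


class TestGaussianKernel:
    def test_identical_lines_give_one(self, tiny_genotypes):
        K = gaussian_kernel(tiny_genotypes, 0.5).values
        assert np.allclose(np.diag(K), 1.0)

    def test_opposite_dh_lines_closed_form(self):
        # opposite at every marker: mean squared difference 4, K = e^{-4h}
        V = np.vstack([np.ones(10), -np.ones(10)])
        K = gaussian_kernel(mm(V), 0.25).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_bandwidth_all_ones(self, tiny_genotypes):
        assert np.allclose(gaussian_kernel(tiny_genotypes, 0.0).values, 1.0)

    def test_negative_bandwidth_errors(self, tiny_genotypes):
        with pytest.raises(ValueError):
            gaussian_kernel(tiny_genotypes, -0.1)

    def test_entries_decrease_with_bandwidth(self, tiny_genotypes):
        K1 = gaussian_kernel(tiny_genotypes, 0.2).values
        K2 = gaussian_kernel(tiny_genotypes, 0.8).values
        off = ~np.eye(tiny_genotypes.n_lines, dtype=bool)
        distinct = K1[off] < 1.0  # non-identical pairs only
        assert np.all(K2[off][distinct] < K1[off][distinct])

    def test_kernel_psd(self, tiny_genotypes):
        eig = np.linalg.eigvalsh(gaussian_kernel(tiny_genotypes, 0.5).values)
        assert eig.min() > -1e-8


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_grm_symmetric_and_kernel_bounded_property(seed):
    rng = np.random.default_rng(seed)
    M = random_marker_matrix(rng, 6, 12)
    K = gaussian_kernel(M, 0.3).values
    assert np.all(K > 0) and np.all(K <= 1 + 1e-12)
    np.testing.assert_allclose(K, K.T)
    p = (M.values.mean(axis=0) + 1) / 2
    if np.any((p > 0) & (p < 1)):
        G = vanraden_grm(M).values
        np.testing.assert_allclose(G, G.T)


def test_vcf_genotype_mapping(tmp_path):
    cyvcf2 = pytest.importorskip("cyvcf2")
    from dhgs.genotypes import read_vcf

    vcf_text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\tm1\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\t./.\n"
        "1\t200\tm2\tG\tC\t.\t.\t.\tGT\t0/1\t0/0\t1/1\n"
    )
    path = tmp_path / "toy.vcf"
    path.write_text(vcf_text)
    M = read_vcf(path)
    assert M.line_ids == ["S1", "S2", "S3"]
    assert M.marker_ids == ["m1", "m2"]
    np.testing.assert_array_equal(M.values[:, 1], [0.0, -1.0, 1.0])
    assert M.values[0, 0] == -1.0 and M.values[1, 0] == 1.0 and np.isnan(M.values[2, 0])


def test_genotype_tsv_round_trip(tmp_path, tiny_genotypes):
    from dhgs.genotypes import read_genotype_tsv, write_genotype_tsv

    cfg = SimConfig(n_lines=5, call_rate_mean=0.7, seed=2)
    masked = mask_genotypes(tiny_genotypes, cfg)
    write_genotype_tsv(masked, tmp_path / "g.tsv")
    back = read_genotype_tsv(tmp_path / "g.tsv")
    assert back.line_ids == masked.line_ids
    np.testing.assert_allclose(back.values, masked.values, atol=1e-5)
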