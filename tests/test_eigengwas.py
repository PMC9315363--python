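import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, spearmanr

from eigensel.eigengwas import (
    CHI2_1_MEDIAN,
    adjust_p,
    count_unique_regions,
    effective_stats,
    eigengwas_scan,
    lambda_gc,
    merge_regions,
    permutation_threshold,
    select_significant,
)
from eigensel.io import qc_filter
from eigensel.relatedness import PCAResult, RelationshipMatrix, pca, standardized_grm
from eigensel.simulate import SimulationConfig, simulate_balding_nichols

from conftest import hwe_matrix, make_matrix


def _pca_from_vector(samples, y):
    y = y / np.linalg.norm(y)
    return PCAResult(
        eigenvalues=np.array([1.0]),
        eigenvectors=y[:, None],
        variance_explained=np.array([1.0]),
        samples=samples,
    )


def oracle_simple_ols(x, y):
    """Closed-form simple regression of y on x: beta, se, chi, p."""
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    beta = np.sum((x - xb) * (y - yb)) / sxx
    alpha = yb - beta * xb
    resid = y - alpha - beta * x
    sigma2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    chi_stat = (beta / se) ** 2
    return beta, se, chi_stat, chi2.sf(chi_stat, 1)


class TestScan:
    def test_equals_closed_form_ols_oracle(self):
        rng = np.random.default_rng(0)
        n, m = 20, 15
        dos = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        mat = make_matrix(dos)
        y = rng.normal(size=n)
        scan = eigengwas_scan(mat, _pca_from_vector(mat.samples, y), k_list=[1])
        yn = y / np.linalg.norm(y)
        for j in range(m):
            if len(set(dos[:, j].tolist())) == 1:
                continue
            beta, se, chi_stat, p = oracle_simple_ols(dos[:, j].astype(float), yn)
            row = scan.iloc[j]
            assert row.beta == pytest.approx(beta, abs=1e-12)
            assert row.se == pytest.approx(se, abs=1e-12)
            assert abs(row.p_raw - p) < 1e-12

    def test_orthogonal_response_gives_null_statistics(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # cov(x, y) = 0
        mat = make_matrix(x[:, None])
        scan = eigengwas_scan(mat, _pca_from_vector(mat.samples, y), k_list=[1])
        assert scan.beta.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert scan.chi.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert scan.p_raw.iloc[0] == pytest.approx(1.0)

    def test_perfect_association_is_maximally_significant(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=200).astype(np.int8)
        y = x - x.mean()
        mat = make_matrix(x[:, None])
        scan = eigengwas_scan(mat, _pca_from_vector(mat.samples, y), k_list=[1], apply_gc=False)
        assert scan.chi.iloc[0] > 1e3
        assert scan.p_raw.iloc[0] == pytest.approx(0.0, abs=1e-200)

    def test_zero_variance_snp_skipped_as_nan(self):
        dos = np.array([[1, 0], [1, 1], [1, 2], [1, 0]], dtype=np.int8)
        mat = make_matrix(dos)
        y = np.array([0.1, 0.4, -0.2, 0.3])
        scan = eigengwas_scan(mat, _pca_from_vector(mat.samples, y), k_list=[1])
        assert np.isnan(scan.chi.iloc[0]) and np.isfinite(scan.chi.iloc[1])

    def test_p_gc_never_smaller_than_p_raw_when_lambda_above_one(self, two_pop_sim):
        matrix, _ = two_pop_sim
        matrix, _ = qc_filter(matrix)
        res = pca(standardized_grm(matrix), k=2)
        scan = eigengwas_scan(matrix, res, k_list=[1, 2])
        for _, sub in scan.groupby("ev"):
            if sub.lambda_gc.iloc[0] >= 1:
                ok = sub.dropna(subset=["p_raw"])
                assert (ok.p_gc >= ok.p_raw - 1e-15).all()


class TestGenomicControl:
    def test_lambda_one_at_reference_median(self):
        assert lambda_gc(np.full(11, CHI2_1_MEDIAN)) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        chi_vals = rng.chisquare(1, 999)
        assert lambda_gc(2 * chi_vals) == pytest.approx(2 * lambda_gc(chi_vals))

    def test_null_chi_square_draws_calibrate_to_one(self):
        rng = np.random.default_rng(3)
        assert lambda_gc(rng.chisquare(1, 100_000)) == pytest.approx(1.0, abs=0.02)

    def test_adjust_p_identity_at_lambda_one(self):
        chi_vals = np.array([0.1, 1.0, 5.0])
        assert np.allclose(adjust_p(chi_vals, 1.0), chi2.sf(chi_vals, 1))

    def test_adjust_p_known_value(self):
        assert adjust_p(np.array([3.84]), 2.0)[0] == pytest.approx(0.1659, abs=2e-4)

    def test_adjust_p_chi_zero_gives_one(self):
        assert adjust_p(np.array([0.0]), 1.7)[0] == 1.0


class TestSelectAndMerge:
    def test_cutoff_boundary(self):
        rec = pd.DataFrame({"minus_log10_p_gc": [5.01, 5.0, 4.99]})
        kept = select_significant(rec, 5.0)
        assert list(kept.minus_log10_p_gc) == [5.01, 5.0]

    def test_single_snp_region_spans_five_mb_flanks(self):
        sig = pd.DataFrame(
            {
                "name": ["2D_16962948"],
                "chrom": ["2D"],
                "pos": [16_962_948],
                "ev": [1],
                "minus_log10_p_gc": [6.2],
            }
        )
        region = merge_regions(sig).iloc[0]
        assert (region.start_mb, region.end_mb) == (11.96, 21.96)
        assert region.top_snp == "2D_16962948"

    def test_transitive_merge_and_separate_regions(self):
        sig = pd.DataFrame(
            {
                "name": ["1A_12000000", "1A_14000000", "1A_30000000"],
                "chrom": ["1A"] * 3,
                "pos": [12_000_000, 14_000_000, 30_000_000],
                "ev": [1] * 3,
                "minus_log10_p_gc": [5.5, 7.0, 6.0],
            }
        )
        regions = merge_regions(sig)
        assert len(regions) == 2
        first = regions.iloc[0]
        assert (first.start_mb, first.end_mb) == (7.0, 19.0)
        assert first.top_snp == "1A_14000000"
        assert first.n_snps == 2

    def test_region_start_floored_at_zero(self):
        sig = pd.DataFrame(
            {
                "name": ["6A_3000000"],
                "chrom": ["6A"],
                "pos": [3_000_000],
                "ev": [9],
                "minus_log10_p_gc": [5.2],
            }
        )
        region = merge_regions(sig).iloc[0]
        assert (region.start_mb, region.end_mb) == (0.0, 8.0)

    def test_ties_resolved_to_smaller_position(self):
        sig = pd.DataFrame(
            {
                "name": ["1A_100", "1A_200"],
                "chrom": ["1A", "1A"],
                "pos": [100, 200],
                "ev": [1, 1],
                "minus_log10_p_gc": [5.5, 5.5],
            }
        )
        assert merge_regions(sig).iloc[0].top_snp == "1A_100"

    def test_evs_kept_separate_but_unique_count_collapses(self):
        sig = pd.DataFrame(
            {
                "name": ["1A_100", "1A_200"],
                "chrom": ["1A", "1A"],
                "pos": [100, 200],
                "ev": [1, 2],
                "minus_log10_p_gc": [5.5, 6.5],
            }
        )
        regions = merge_regions(sig)
        assert len(regions) == 2
        assert count_unique_regions(regions) == 1

    def test_per_snp_fst_attached_to_representative(self):
        sig = pd.DataFrame(
            {
                "name": ["3B_500"],
                "chrom": ["3B"],
                "pos": [500],
                "ev": [2],
                "minus_log10_p_gc": [8.0],
            }
        )
        fst = pd.DataFrame({"name": ["3B_500"], "theta": [0.42]})
        assert merge_regions(sig, per_snp_fst=fst).iloc[0].fst == pytest.approx(0.42)


class TestPermutationThreshold:
    def _null_panel(self, n, m, seed):
        mat = hwe_matrix(n, m, seed=seed)
        res = pca(standardized_grm(mat), k=1)
        return mat, res

    def test_deterministic_under_seed(self):
        mat, res = self._null_panel(30, 150, seed=4)
        t1 = permutation_threshold(mat, res, n_perm=120, rng=7)
        t2 = permutation_threshold(mat, res, n_perm=120, rng=7)
        assert t1 == t2

    def test_threshold_grows_with_snp_count(self):
        mat_s, res_s = self._null_panel(50, 400, seed=5)
        mat_l, res_l = self._null_panel(50, 2000, seed=5)
        t_small = permutation_threshold(mat_s, res_s, n_perm=150, rng=1)
        t_large = permutation_threshold(mat_l, res_l, n_perm=150, rng=1)
        assert t_large > t_small

    def test_fresh_null_permutations_beat_threshold_about_five_percent(self):
        from eigensel.eigengwas import _ols_scan

        mat, res = self._null_panel(40, 250, seed=6)
        thr = permutation_threshold(mat, res, n_perm=200, rng=11)
        p_thr = 10 ** (-thr)
        rng = np.random.default_rng(99)
        y = res.eigenvectors[:, 0]
        X = mat.dosages.astype(float)
        called = mat.dosages != -1
        count = 0
        n_fresh = 200
        for _ in range(n_fresh):
            yp = rng.permutation(y)
            _, _, chi_stat = _ols_scan(X, called, yp)
            p_gc = adjust_p(chi_stat, lambda_gc(chi_stat))
            if np.nanmin(p_gc) <= p_thr:
                count += 1
        assert 2 <= count <= 25  # binomial(200, 0.05): mean 10, sd ~3.1


class TestEffectiveStats:
    def _grm_with_offdiag(self, n, g):
        vals = np.full((n, n), g)
        np.fill_diagonal(vals, 1.0)
        return RelationshipMatrix(np.arange(n).astype(object), vals, "standardized_grm")

    def test_reference_mean_relatedness_maps_to_effective_size(self):
        stats = effective_stats(self._grm_with_offdiag(422, -0.0046))
        assert stats["n_e"] == pytest.approx(217.39, abs=0.01)

    def test_exact_identity_grm(self):
        n = 50
        stats = effective_stats(self._grm_with_offdiag(n, -1.0 / (n - 1)))
        assert stats["n_e"] == pytest.approx(n - 1)

    def test_hwe_panel_effective_size_near_n(self):
        mat = hwe_matrix(120, 4000, seed=8)
        stats = effective_stats(standardized_grm(mat))
        assert stats["n_e"] == pytest.approx(120, rel=0.1)
        assert stats["m_e"] > 100

    def test_selfing_panel_effective_size_near_half_n(self):
        # inbred accessions have GRM diagonal ~ 2, so n_e ~ n/2 — the
        # behavior real selfing wheat panels show
        cfg = SimulationConfig(n_per_subpop=(200,), n_snps=3000, n_selected=0, seed=9)
        matrix, _ = simulate_balding_nichols(cfg)
        matrix, _ = qc_filter(matrix)
        stats = effective_stats(standardized_grm(matrix))
        assert stats["n_e"] == pytest.approx(100, rel=0.1)


def test_miami_concordance_fst_mirrors_scan(two_pop_sim):
    from eigensel.fst import wc_fst_per_snp

    matrix, _ = two_pop_sim
    matrix, _ = qc_filter(matrix)
    res = pca(standardized_grm(matrix), k=1)
    scan = eigengwas_scan(matrix, res, k_list=[1])
    fst = wc_fst_per_snp(matrix)
    merged = scan.merge(fst[["name", "theta"]], on="name").dropna(subset=["theta", "minus_log10_p_gc"])
    rho = spearmanr(merged.minus_log10_p_gc, merged.theta).statistic
    assert rho > 0.6
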