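"""Diversity estimators against closed forms and Monte-Carlo oracles."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lakebrowning.errors import (
    DegenerateColumnError,
    EstimatorUndefinedError,
    InvalidDepthError,
    NoSolutionError,
    UndefinedDistanceError,
    ZeroRowError,
)
from lakebrowning.metrics import (
    ace_richness,
    alpha_diversity,
    bray_curtis,
    cdom_pca_index,
    fisher_alpha,
    hellinger_transform,
    rarefy_expected,
    rarefy_subsample,
    species_accum_exact,
)

count_matrices = arrays(
    np.int64, st.tuples(st.integers(2, 6), st.integers(2, 8)),
    elements=st.integers(0, 50),
).filter(lambda m: (m.sum(axis=1) > 0).all())


class TestHellinger:
    def test_worked_rows(self):
        out = hellinger_transform(np.array([[1, 1, 2], [5, 0, 0]]))
        assert np.allclose(out.iloc[0], [0.5, 0.5, 0.70711], atol=1e-5)
        assert np.allclose(out.iloc[1], [1.0, 0.0, 0.0])

    def test_zero_row_names_site(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"])
        with pytest.raises(ZeroRowError, match="b"):
            hellinger_transform(counts)

    @settings(max_examples=50, deadline=None)
    @given(count_matrices)
    def test_rows_on_unit_sphere(self, mat):
        out = hellinger_transform(mat).to_numpy()
        assert np.allclose((out**2).sum(axis=1), 1.0, atol=1e-12)


class TestBrayCurtis:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 0], [0, 1], 1.0),
        ([3, 2, 1], [3, 2, 1], 0.0),
        ([2, 2], [1, 3], 0.25),
    ])
    def test_worked_pairs(self, x, y, expected):
        d = bray_curtis(np.array([x, y], dtype=float))
        assert d.iloc[0, 1] == pytest.approx(expected)

    def test_two_zero_rows_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            bray_curtis(np.array([[0, 0], [0, 0], [1, 2]]))

    @settings(max_examples=40, deadline=None)
    @given(count_matrices)
    def test_metric_properties_and_zero_column_invariance(self, mat):
        d = bray_curtis(mat).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        padded = np.hstack([mat, np.zeros((mat.shape[0], 3), dtype=int)])
        assert np.allclose(bray_curtis(padded).to_numpy(), d)

    def test_matches_scikit_bio(self, rng):
        from skbio.diversity import beta_diversity

        mat = rng.integers(0, 40, size=(8, 15))
        mat[mat.sum(axis=1) == 0, 0] = 1
        ours = bray_curtis(mat).to_numpy()
        theirs = beta_diversity("braycurtis", mat).data
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_hellinger_rows_still_in_unit_range(self, rng):
        mat = rng.integers(1, 30, size=(6, 10))
        d = bray_curtis(hellinger_transform(mat)).to_numpy()
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestAlpha:
    def test_uniform_composition(self):
        res = alpha_diversity(np.array([[1, 1, 1, 1]]),
                              ("richness", "shannon", "inv_simpson"))
        assert res["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert res["inv_simpson"].iloc[0] == pytest.approx(4.0)

    def test_single_taxon(self):
        res = alpha_diversity(np.array([[7, 0, 0]]),
                              ("richness", "shannon", "simpson"))
        assert res.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_shannon_maximal_at_uniform(self, rng):
        s = 6
        uniform = alpha_diversity(np.full((1, s), 10), "shannon").iloc[0, 0]
        for _ in range(20):
            row = rng.integers(1, 50, size=(1, s))
            assert alpha_diversity(row, "shannon").iloc[0, 0] <= uniform + 1e-12

    def test_inverse_simpson_bounded_by_richness(self, rng):
        row = rng.integers(0, 30, size=(1, 12))
        row[0, 0] = max(row[0, 0], 1)
        res = alpha_diversity(row, ("richness", "inv_simpson"))
        assert res["inv_simpson"].iloc[0] <= res["richness"].iloc[0] + 1e-9

    def test_fisher_alpha_matches_grid_scan(self):
        s_obs, n = 20, 100
        grid = np.linspace(1e-3, 100, 2_000_000)
        vals = grid * np.log1p(n / grid) - s_obs
        root = grid[np.argmin(np.abs(vals))]
        assert fisher_alpha(s_obs, n) == pytest.approx(root, abs=1e-3)

    def test_fisher_no_solution(self):
        with pytest.raises(NoSolutionError):
            fisher_alpha(5, 5)  # all singletons
        with pytest.raises(NoSolutionError):
            fisher_alpha(1, 50)


class TestAce:
    def test_no_rare_taxa_returns_observed(self):
        res = ace_richness(np.array([20, 30, 40]))
        assert res.ace == res.s_obs == 3

    def test_worked_example_matches_exact_fraction(self):
        # independent evaluation of the Chao-Lee formula in exact arithmetic:
        # rare = (1,1,2,3): S_rare=4, N_rare=7, F1=2, C = 5/7,
        # gamma^2 = max((4/C) * 8/42 - 1, 0) = 1/15,
        # ACE = 1 + 4/C + (2/C)(1/15) = 509/75
        expected = Fraction(1) + Fraction(4 * 7, 5) + Fraction(2 * 7, 5) * Fraction(1, 15)
        assert expected == Fraction(509, 75)
        res = ace_richness(np.array([1, 1, 2, 3, 12]))
        assert res.ace == pytest.approx(float(expected), abs=1e-12)
        assert res.c_ace == pytest.approx(5 / 7)
        assert res.f1 == 2 and res.s_abund == 1 and res.s_rare == 4

    def test_all_singletons_undefined(self):
        with pytest.raises(EstimatorUndefinedError):
            ace_richness(np.array([1, 1, 1]))


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        assert rarefy_expected([5, 3, 2], 10) == pytest.approx(3.0)

    def test_two_taxon_worked_example(self):
        assert rarefy_expected([4, 1], 2) == pytest.approx(1.4)

    def test_depth_one_gives_one(self):
        assert rarefy_expected([10, 5, 1], 1) == pytest.approx(1.0)

    def test_nondecreasing_in_depth(self):
        row = [50, 30, 20, 1]
        vals = [rarefy_expected(row, n) for n in range(1, 102, 10)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_matches_monte_carlo(self):
        row = np.array([50, 30, 20])
        depth, reps = 25, 10_000
        rng = np.random.default_rng(0)
        richness = np.array([
            (rng.multivariate_hypergeometric(row, depth) > 0).sum()
            for _ in range(reps)
        ])
        se = richness.std(ddof=1) / np.sqrt(reps)
        assert abs(rarefy_expected(row, depth) - richness.mean()) < 3 * se

    def test_invalid_depth(self):
        with pytest.raises(InvalidDepthError):
            rarefy_expected([3, 2], 6)


class TestSubsample:
    def test_defaults_to_min_row_sum(self):
        counts = np.array([[10, 10], [3, 2]])
        out = rarefy_subsample(counts, seed=0)
        assert (out.sum(axis=1) == 5).all()

    def test_full_depth_row_unchanged(self):
        counts = np.array([[4, 6]])
        out = rarefy_subsample(counts, depth=10, seed=1)
        assert out.iloc[0].tolist() == [4, 6]

    def test_cells_never_exceed_original(self, rng):
        counts = rng.integers(0, 20, size=(4, 6)) + 1
        out = rarefy_subsample(counts, depth=5, seed=2)
        assert (out.to_numpy() <= counts).all()

    def test_matches_hypergeometric_mean(self):
        counts = np.array([[12, 8, 4]])
        depth, reps = 10, 5_000
        draws = np.vstack([
            rarefy_subsample(counts, depth, seed=s).to_numpy() for s in range(reps)
        ])
        expected = depth * counts[0] / counts.sum()
        var = depth * (counts[0] / 24) * (1 - counts[0] / 24) * (24 - depth) / 23
        se = np.sqrt(var / reps)
        assert (np.abs(draws.mean(axis=0) - expected) < 4 * se).all()

    def test_depth_above_row_sum_names_site(self):
        counts = pd.DataFrame([[5, 5], [1, 1]], index=["deep", "shallow"])
        with pytest.raises(InvalidDepthError, match="shallow"):
            rarefy_subsample(counts, depth=6)


class TestAccumulation:
    def test_ubiquitous_taxon_contributes_one(self):
        counts = np.array([[1, 0], [2, 0], [3, 5]])
        curve = species_accum_exact(counts)
        assert curve.expected_richness[-1] == pytest.approx(2.0)
        base = species_accum_exact(counts[:, :1])
        assert np.allclose(base.expected_richness, 1.0)

    def test_first_point_is_mean_site_richness(self, rng):
        mat = rng.integers(0, 3, size=(6, 12))
        mat[mat.sum(axis=1) == 0, 0] = 1
        curve = species_accum_exact(mat)
        assert curve.expected_richness[0] == pytest.approx(
            (mat > 0).sum(axis=1).mean()
        )

    def test_matches_permutation_mean(self, rng):
        mat = rng.integers(0, 4, size=(6, 10))
        mat[mat.sum(axis=1) == 0, 0] = 1
        curve = species_accum_exact(mat)
        reps = 2_000
        occ = mat > 0
        sums = np.zeros(6)
        sums_sq = np.zeros(6)
        for _ in range(reps):
            perm = rng.permutation(6)
            seen = np.cumsum(occ[perm], axis=0) > 0
            richness = seen.sum(axis=1)
            sums += richness
            sums_sq += richness.astype(float) ** 2
        mean = sums / reps
        se = np.sqrt((sums_sq / reps - mean**2) / reps)
        assert np.all(np.abs(curve.expected_richness - mean) <= 3 * se + 1e-9)
        assert np.all(np.diff(curve.expected_richness) >= -1e-12)


class TestCdomPca:
    def test_rank_one_spectra_give_pc1_everything(self, rng):
        base = np.exp(-0.015 * np.arange(351))
        scales = rng.uniform(0.5, 3.0, size=8)
        spectra = scales[:, None] * base[None, :]
        idx = cdom_pca_index(spectra, scale=False)
        assert idx.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition(self, rng):
        spectra = rng.normal(5.0, 1.0, size=(12, 40)) ** 2
        idx = cdom_pca_index(spectra, n_components=4, scale=True)
        z = (spectra - spectra.mean(0)) / spectra.std(0)
        cov = np.cov(z, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fracs = evals / evals.sum()
        assert np.allclose(idx.variance_fractions, fracs[:4], atol=1e-9)
        scores = z @ np.linalg.eigh(cov)[1][:, ::-1][:, :4]
        for k in range(4):
            r = abs(np.corrcoef(scores[:, k], idx.scores.iloc[:, k])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_rows_leave_fractions_unchanged(self, rng):
        spectra = rng.uniform(1, 2, size=(6, 20))
        a = cdom_pca_index(spectra, n_components=3).variance_fractions
        b = cdom_pca_index(np.vstack([spectra, spectra]),
                           n_components=3).variance_fractions
        assert np.allclose(a, b, atol=1e-9)

    def test_pc1_oriented_with_absorbance(self, standard_dataset):
        idx = cdom_pca_index(standard_dataset.spectra)
        mean_abs = standard_dataset.spectra.mean(axis=1)
        assert np.corrcoef(idx.scores["pc1"], mean_abs)[0, 1] > 0.9

    def test_constant_column_rejected(self):
        spectra = np.ones((5, 10))
        spectra[:, :5] = np.random.default_rng(0).uniform(1, 2, size=(5, 5))
        with pytest.raises(DegenerateColumnError):
            cdom_pca_index(spectra, scale=True)
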