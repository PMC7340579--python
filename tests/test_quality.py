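import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdbq import (
    compute_q1,
    fit_geometry_pca,
    mice_impute,
    percentile_rank,
    q1p_approx,
    score_geometry,
)
from pdbq.quality import GEOMETRY_METRICS


class TestPercentileRank:
    def test_hand_ranked_example(self):
        result = percentile_rank([10, 20, 20, 40], better="lower")
        assert result == pytest.approx([100, 62.5, 62.5, 25])

    def test_single_value_scores_100(self):
        assert percentile_rank([5.0]) == pytest.approx([100.0])

    def test_all_tied_share_percentile(self):
        assert percentile_rank([3, 3, 3, 3]) == pytest.approx([62.5] * 4)

    def test_orientation_flips_ranks(self):
        low = percentile_rank([1, 2, 3], better="lower")
        high = percentile_rank([1, 2, 3], better="higher")
        assert low == pytest.approx(high[::-1])

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            percentile_rank([])

    def test_matches_brute_force_definition(self):
        """Against an O(N^2) count-based oracle: percentile of v is
        100 * (|{u: u worse}| + (|ties|+1)/2) / N."""
        rng = np.random.default_rng(0)
        values = rng.integers(0, 50, 500).astype(float)  # many ties
        result = percentile_rank(values, better="lower")
        for idx in rng.choice(500, 25, replace=False):
            v = values[idx]
            worse = np.sum(values > v)
            ties = np.sum(values == v)
            expected = 100.0 * (worse + (ties + 1) / 2.0) / len(values)
            assert result[idx] == pytest.approx(expected)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_percentile_law(self, values):
        """Percentiles lie in (0, 100] and average exactly 100(N+1)/(2N)."""
        result = percentile_rank(values)
        n = len(values)
        assert np.all(result > 0) and np.all(result <= 100)
        assert result.mean() == pytest.approx(100 * (n + 1) / (2 * n))

    def test_midpoint_convention(self):
        result = percentile_rank([1, 2], better="lower", convention="midpoint")
        assert result == pytest.approx([75.0, 25.0])


class TestGeometryPCA:
    def _frame(self, clash, rama, rota):
        return pd.DataFrame(
            {
                "pdb_id": [f"1{i:03d}" for i in range(len(clash))],
                "molecule_class": "protein",
                "clashscore": clash,
                "rama_outliers": rama,
                "rota_outliers": rota,
            }
        )

    def test_identical_columns_give_equal_loadings(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        model = fit_geometry_pca(self._frame(base, base, base))
        assert model.explained_variance_fractions[0] == pytest.approx(1.0)
        assert model.loadings[:, 0] == pytest.approx([1 / np.sqrt(3)] * 3)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=80)
        frame = self._frame(
            5 + 2 * latent + rng.normal(size=80),
            0.5 + 0.3 * latent + 0.2 * rng.normal(size=80),
            3 + latent + 0.5 * rng.normal(size=80),
        )
        model = fit_geometry_pca(frame)
        z = (frame[GEOMETRY_METRICS] - frame[GEOMETRY_METRICS].mean()) / frame[
            GEOMETRY_METRICS
        ].std(ddof=1)
        eigvals, eigvecs = np.linalg.eigh(np.cov(z.to_numpy(), rowvar=False))
        order = np.argsort(eigvals)[::-1]
        expected_fracs = eigvals[order] / eigvals.sum()
        assert model.explained_variance_fractions == pytest.approx(expected_fracs, abs=1e-10)
        for j in range(3):
            v = eigvecs[:, order[j]]
            assert min(
                np.abs(model.loadings[:, j] - v).max(),
                np.abs(model.loadings[:, j] + v).max(),
            ) < 1e-10

    def test_sklearn_cross_check(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        latent = rng.normal(size=120)
        frame = self._frame(
            6 + 3 * latent + rng.normal(size=120),
            0.4 + 0.5 * latent + 0.3 * rng.normal(size=120),
            2 + 1.5 * latent + rng.normal(size=120),
        )
        model = fit_geometry_pca(frame)
        z = (frame[GEOMETRY_METRICS] - model.means) / model.sds
        ref = PCA(n_components=3).fit(z.to_numpy())
        assert model.explained_variance_fractions == pytest.approx(
            ref.explained_variance_ratio_, abs=1e-10
        )

    def test_outliers_excluded_from_fit_but_scored(self):
        frame = self._frame(
            [1, 2, 3, 4, 5, 300.0],
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            [1, 2, 3, 4, 5, 6],
        )
        model = fit_geometry_pca(frame)
        assert model.outlier_ids == ["1005"]
        scores = score_geometry(model, frame)
        assert len(scores) == 6
        assert scores[-1] == max(scores)  # worst deposit gets the worst score

    def test_pc1_nonnegative_loadings(self, medium_synthetic):
        completed = mice_impute(medium_synthetic, seed=0).completed
        protein = completed[completed["molecule_class"] != "nucleic_acid"]
        model = fit_geometry_pca(protein)
        assert (model.loadings[:, 0] >= 0).all()
        assert np.all(np.diff(model.explained_variance_fractions) <= 0)

    def test_zero_variance_is_error(self):
        frame = self._frame([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="zero variance"):
            fit_geometry_pca(frame)

    def test_centered_input_scores_zero(self):
        frame = self._frame([1, 2, 3, 4.0], [0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4.0])
        model = fit_geometry_pca(frame)
        center = pd.DataFrame(
            {
                "clashscore": [model.means[0]],
                "rama_outliers": [model.means[1]],
                "rota_outliers": [model.means[2]],
            }
        )
        assert score_geometry(model, center)[0] == pytest.approx(0.0)

    def test_worsening_clashscore_increases_score(self):
        frame = self._frame([1, 2, 3, 4.0], [0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4.0])
        model = fit_geometry_pca(frame)
        a = pd.DataFrame({"clashscore": [2.0], "rama_outliers": [0.2], "rota_outliers": [2.0]})
        b = a.assign(clashscore=4.0)
        assert score_geometry(model, b)[0] > score_geometry(model, a)[0]


@pytest.fixture(scope="module")
def scored(medium_synthetic):
    completed = mice_impute(medium_synthetic, seed=0).completed
    return completed, compute_q1(completed)


class TestCompositeScores:
    def test_equal_components_identity(self):
        for p in (10.0, 55.0, 100.0):
            assert q1p_approx(p, p, p, p, p) == pytest.approx(p)

    def test_min_variant_bounded_by_average(self, scored):
        _, scores = scored
        assert (scores["q1_min"] <= scores["q1"] + 1e-12).all()

    def test_component_arithmetic(self):
        # (30, 60, 90): averaging gives 60, minimum gives 30.
        comps = np.array([30.0, 60.0, 90.0])
        assert comps.mean() == pytest.approx(60.0)
        assert comps.min() == pytest.approx(30.0)

    def test_groups_are_disjoint_populations(self, scored):
        _, scores = scored
        for group in ("protein", "nucleic"):
            sub = scores[scores["group"] == group]
            n = len(sub)
            assert sub["p_q1"].mean() == pytest.approx(100 * (n + 1) / (2 * n))

    def test_complexes_scored_in_protein_group(self, scored):
        completed, scores = scored
        complexes = completed["molecule_class"] == "complex"
        assert (scores.loc[complexes, "group"] == "protein").all()

    def test_missing_metric_is_error(self, medium_synthetic):
        with pytest.raises(ValueError, match="impute"):
            compute_q1(medium_synthetic)

    def test_improving_component_never_decreases_q1(self, scored):
        """Lowering one deposit's R_free (others fixed) must not lower its
        composite score or final percentile."""
        completed, scores = scored
        target = completed.index[10]
        better = completed.copy()
        better.loc[target, "r_free"] = better["r_free"].min() / 2
        rescored = compute_q1(better)
        assert rescored.loc[target, "q1"] >= scores.loc[target, "q1"] - 1e-9
        assert rescored.loc[target, "p_q1"] >= scores.loc[target, "p_q1"] - 1e-9


class TestApproximation:
    def test_direct_substitution(self):
        assert q1p_approx(100.0, 100.0, 0.1, 0.1, 0.1) == pytest.approx(66.7, abs=0.05)

    def test_out_of_range_components_error(self):
        with pytest.raises(ValueError):
            q1p_approx(0.0, 50.0, 50.0, 50.0, 50.0)
        with pytest.raises(ValueError):
            q1p_approx(101.0, 50.0, 50.0, 50.0, 50.0)

    def test_tracks_exact_composite_on_synthetic_proteins(self, scored):
        """The equal-weight approximation correlates with the PCA-based
        composite (Spearman > 0.95) because the PC1 loadings are near
        equal."""
        from scipy import stats

        from pdbq.quality import percentile_rank

        completed, scores = scored
        protein = scores["group"] == "protein"
        sub = completed[protein]
        approx = q1p_approx(
            percentile_rank(sub["r_free"], better="lower"),
            percentile_rank(sub["rsrz_outliers"], better="lower"),
            percentile_rank(sub["clashscore"], better="lower"),
            percentile_rank(sub["rama_outliers"], better="lower"),
            percentile_rank(sub["rota_outliers"], better="lower"),
        )
        rho = stats.spearmanr(approx, scores.loc[protein, "q1"]).statistic
        assert rho > 0.95
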