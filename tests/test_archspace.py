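"""Architecture clouds, ANOSIM, and the sensitivity decomposition."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from caparch import (
    ParameterError,
    RegionEstimates,
    anosim,
    dominant_component,
    drifted_freq_scenario,
    gvp_vector,
    heterogeneous_beta_scenario,
    pairwise_distances,
    regional_association,
    resample_gvp_cloud,
    sensitivity_decomposition,
    simulate_counts,
)


class TestResampleGvpCloud:
    def test_no_noise_limit_reproduces_point_estimate(self, rng):
        freqs = np.array([0.2, 0.5, 0.7])
        betas = np.array([0.3, 0.1, -0.2])
        cloud = resample_gvp_cloud(freqs, [np.inf] * 3, betas, [0.0] * 3,
                                   b_resamples=10, mode="both", rng=rng)
        point = gvp_vector(freqs, betas).values
        assert np.allclose(cloud.matrix, point)

    def test_beta_only_keeps_frequencies_fixed(self, rng):
        freqs = np.array([0.2, 0.5])
        betas = np.array([0.3, 0.1])
        cloud = resample_gvp_cloud(freqs, [2000, 2000], betas, [0.0, 0.0],
                                   b_resamples=8, mode="beta_only", rng=rng)
        # zero effect noise in beta_only mode: rows must be identical,
        # proving frequencies were not resampled either
        assert np.allclose(cloud.matrix, cloud.matrix[0])

    def test_rows_sum_to_one(self, rng):
        cloud = resample_gvp_cloud([0.3, 0.6], [500, 500], [0.2, -0.1],
                                   [0.05, 0.05], b_resamples=50, rng=rng)
        assert np.allclose(cloud.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_centroid_converges_to_point_estimate(self, rng):
        freqs = np.array([0.2, 0.5, 0.7, 0.4])
        betas = np.array([0.3, 0.15, -0.2, 0.25])
        cloud = resample_gvp_cloud(freqs, [np.inf] * 4, betas, [0.01] * 4,
                                   b_resamples=10_000, mode="beta_only", rng=rng)
        point = gvp_vector(freqs, betas).values
        assert np.linalg.norm(cloud.centroid - point) < 5e-3

    def test_invalid_mode_rejected(self, rng):
        with pytest.raises(ParameterError):
            resample_gvp_cloud([0.5], [100], [0.1], [0.1], mode="nope", rng=rng)


class TestPairwiseDistances:
    def test_closed_forms(self):
        d = pairwise_distances([[0, 1], [1, 0]])
        assert d == pytest.approx([np.sqrt(2)])
        assert pairwise_distances([[0.5, 0.5], [0.5, 0.5]]) == pytest.approx([0.0])

    def test_collinear_points(self):
        d = pairwise_distances([[0.0], [1.0], [3.0]])
        assert sorted(d.tolist()) == pytest.approx([1.0, 2.0, 3.0])


class TestAnosim:
    def test_perfect_separation_gives_r_one(self, rng):
        points = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]])
        res = anosim(pairwise_distances(points), ["a", "a", "b", "b"],
                     n_perm=99, rng=rng)
        assert res.r == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0], [10.5], [0.4]])
        labels = np.array(["a", "a", "b", "b", "b", "a"])
        res = anosim(pdist(points), labels, method="exact")

        # independent enumeration over all 6! label orders
        ranks = rankdata(pdist(points))
        i_idx, j_idx = np.triu_indices(6, k=1)

        def r_stat(lab):
            within = lab[i_idx] == lab[j_idx]
            return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)

        rs = [r_stat(labels[list(perm)])
              for perm in itertools.permutations(range(6))]
        expected_p = np.mean([r >= res.r - 1e-12 for r in rs])
        assert res.p == pytest.approx(expected_p)
        assert res.r == pytest.approx(r_stat(labels))

    def test_sampled_p_approximates_exact(self, rng):
        points = rng.normal(size=(8, 2))
        labels = ["a"] * 4 + ["b"] * 4
        exact = anosim(pdist(points), labels, method="exact")
        sampled = anosim(pdist(points), labels, n_perm=4999, rng=rng)
        assert sampled.p == pytest.approx(exact.p, abs=0.03)

    def test_rank_invariance_under_monotone_transform(self, rng):
        points = rng.normal(size=(9, 3))
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        d = pdist(points)
        r1 = anosim(d, labels, n_perm=9, rng=np.random.default_rng(0)).r
        r2 = anosim(d ** 2, labels, n_perm=9, rng=np.random.default_rng(0)).r
        r3 = anosim(np.log(d), labels, n_perm=9, rng=np.random.default_rng(0)).r
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_p_floor(self, rng):
        # perfectly separated 5+5 points: p is small but can never
        # drop below 1/(1 + n_perm); permutations that recreate the
        # same partition tie with the observed R and count against it
        points = np.vstack([np.zeros((5, 2)), np.full((5, 2), 9.0)])
        points += rng.normal(scale=0.01, size=points.shape)
        res = anosim(pdist(points), ["a"] * 5 + ["b"] * 5, n_perm=99, rng=rng)
        assert res.p >= 1 / 100
        assert res.p <= 0.05

    def test_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim
        points = rng.normal(size=(10, 4))
        labels = ["a"] * 5 + ["b"] * 5
        ours = anosim(pdist(points), labels, n_perm=9, rng=rng)
        ref = skbio_anosim(DistanceMatrix(squareform_from(points)), grouping=labels,
                           permutations=0)
        assert ours.r == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ParameterError):
            anosim(pdist(np.random.default_rng(0).normal(size=(3, 2))),
                   ["a", "a", "b"], n_perm=9, rng=rng)


def squareform_from(points):
    from scipy.spatial.distance import squareform
    return squareform(pdist(points))


def _estimates(cfg, rep_seed=0):
    counts = simulate_counts(cfg, rng=np.random.default_rng([77, rep_seed]))
    assoc = regional_association(counts)
    return {r: RegionEstimates(s["FREQ"].to_numpy(), s["CtrlTotal"].to_numpy(float),
                               s["BETA"].to_numpy(), s["SE"].to_numpy())
            for r, s in assoc.groupby("Region", sort=False)}


class TestSensitivityDecomposition:
    def test_region_specific_effects_name_effect_sizes(self):
        cfg = heterogeneous_beta_scenario(m_variants=60, n_hetero=10,
                                          delta_beta=0.25, seed=21)
        table = sensitivity_decomposition(_estimates(cfg), 400,
                                          rng=np.random.default_rng(1))
        assert dominant_component(table) == "effect_sizes"
        # effect-size clouds sit further apart than frequency clouds
        assert (table["mean_dist_beta"] > table["mean_dist_freq"]).all()
        assert (table.loc[table["dominant"] == "effect_sizes", "t_p"] < 1e-6).all()

    def test_drifted_frequencies_name_allele_frequencies(self):
        # large cohorts shrink effect-size noise so the drifted
        # frequencies are the only real source of separation
        sizes = {r: (100_000, 100_000) for r in ("West", "East", "South")}
        cfg = drifted_freq_scenario(m_variants=60, f_drift=0.1, seed=22,
                                    region_sizes=sizes)
        table = sensitivity_decomposition(_estimates(cfg), 400,
                                          rng=np.random.default_rng(2))
        assert dominant_component(table) == "allele_frequencies"
        assert (table["mean_dist_freq"] > table["mean_dist_beta"]).all()

    def test_zero_noise_identical_regions_degenerate(self):
        est = RegionEstimates(np.array([0.3, 0.6]), np.array([np.inf, np.inf]),
                              np.array([0.2, 0.1]), np.array([0.0, 0.0]))
        table = sensitivity_decomposition({"A": est, "B": est}, 50,
                                          rng=np.random.default_rng(3))
        assert bool(table["degenerate"].all())
        assert table["dominant"].tolist() == ["degenerate"]
        assert np.isnan(table["t_stat"]).all()

    def test_b_too_small_rejected(self):
        est = RegionEstimates(np.array([0.3]), np.array([100.0]),
                              np.array([0.2]), np.array([0.1]))
        with pytest.raises(ParameterError):
            sensitivity_decomposition({"A": est, "B": est}, 1)
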