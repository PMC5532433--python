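import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from halocrust.abundance import AbundanceMatrix
from halocrust.config import EcologyParams
from halocrust.ecology import (
    DistanceMatrix,
    bioenv,
    bray_curtis,
    mantel,
    mrpp,
    nmds,
    permanova,
    _within_group_delta,
    _permanova_f,
)


def _matrix(columns: dict[str, list[float]]) -> AbundanceMatrix:
    values = pd.DataFrame(columns)
    values.index = [f"org{i}" for i in range(len(values))]
    return AbundanceMatrix(values=values, total_reads={c: 1 for c in values.columns})


def _dm(values, labels=None) -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(values))]
    return DistanceMatrix(labels=labels, values=values)


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        d = bray_curtis(_matrix({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        d = bray_curtis(_matrix({"a": [1, 2, 0, 0], "b": [0, 0, 3, 1]}))
        assert d.values[0, 1] == 1.0

    def test_hand_computed_third(self):
        d = bray_curtis(_matrix({"a": [1, 1], "b": [3, 1]}))
        assert d.values[0, 1] == pytest.approx(2 / 6)

    def test_matches_scipy_on_random_data(self, rng):
        data = {f"s{i}": rng.random(12) * 5 for i in range(6)}
        d = bray_curtis(_matrix(data))
        cols = list(data)
        for i, j in itertools.combinations(range(6), 2):
            assert d.values[i, j] == pytest.approx(
                scipy_braycurtis(data[cols[i]], data[cols[j]])
            )

    def test_two_all_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="z1.*z2"):
            bray_curtis(_matrix({"z1": [0, 0], "z2": [0, 0], "a": [1, 2]}))


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        d = _dm(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        res = nmds(d, EcologyParams(nmds_starts=5), seed=0)
        assert res.stress < 1e-3
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_planar_points_recovered_below_stress_001(self, rng):
        points = rng.random((6, 2)) * 10
        d = _dm(squareform(pdist(points)))
        res = nmds(d, EcologyParams(nmds_starts=10), seed=1)
        assert res.stress < 0.01

    def test_deterministic_given_seed(self, rng):
        points = rng.random((7, 2)) * 3
        d = _dm(squareform(pdist(points)))
        a = nmds(d, EcologyParams(nmds_starts=5), seed=3)
        b = nmds(d, EcologyParams(nmds_starts=5), seed=3)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_site_clusters_separate_in_ordination(self, rng):
        # three tight clusters of three samples each
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        pts = np.vstack([c + rng.normal(0, 0.3, (3, 2)) for c in centers])
        d = _dm(squareform(pdist(pts)))
        res = nmds(d, EcologyParams(nmds_starts=10), seed=0)
        coords = res.coordinates
        groups = np.repeat([0, 1, 2], 3)
        within, between = [], []
        for i, j in itertools.combinations(range(9), 2):
            dist = np.linalg.norm(coords[i] - coords[j])
            (within if groups[i] == groups[j] else between).append(dist)
        assert np.mean(within) < np.mean(between)

    def test_k_too_large_rejected(self):
        d = _dm(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="nmds_k"):
            nmds(d, EcologyParams(nmds_k=2, nmds_starts=2), seed=0)


def exhaustive_mrpp_p(d, labels):
    """All distinct label permutations, delta <= observed, add-one convention."""
    labels = np.asarray(labels)
    delta_obs = _within_group_delta(d, labels)
    deltas = [
        _within_group_delta(d, np.asarray(perm))
        for perm in set(itertools.permutations(labels))
    ]
    return sum(1 for x in deltas if x <= delta_obs + 1e-12) / len(deltas)


class TestMrpp:
    def _clustered(self, rng, spread=0.1):
        pts = np.vstack([
            [0, 0] + rng.normal(0, spread, (3, 2)),
            [5, 5] + rng.normal(0, spread, (3, 2)),
        ])
        return squareform(pdist(pts))

    def test_random_labels_give_A_near_zero(self, rng):
        d = squareform(pdist(rng.random((12, 3))))
        labels = list("aabbab" * 2)
        res = mrpp(_dm(d), labels, EcologyParams(n_permutations=499), seed=0)
        assert abs(res.observed) < 0.25
        assert res.p_value > 0.01

    def test_perfect_separation_hits_p_floor(self, rng):
        # groups large enough that a permutation recreating the observed
        # split is essentially impossible, so only the add-one term remains
        pts = np.vstack([
            [0, 0] + rng.normal(0, 1e-6, (8, 2)),
            [5, 5] + rng.normal(0, 1e-6, (8, 2)),
        ])
        d = squareform(pdist(pts))
        res = mrpp(_dm(d), ["a"] * 8 + ["b"] * 8,
                   EcologyParams(n_permutations=999), seed=0)
        assert res.observed > 0
        assert res.p_value == pytest.approx(1 / 1000)

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        d = self._clustered(rng, spread=0.8)
        labels = ["a"] * 3 + ["b"] * 3
        res = mrpp(_dm(d), labels, EcologyParams(n_permutations=999), seed=5)
        exact = exhaustive_mrpp_p(d, labels)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_singleton_group_rejected(self, rng):
        d = squareform(pdist(rng.random((4, 2))))
        with pytest.raises(ValueError, match="fewer than 2"):
            mrpp(_dm(d), ["a", "a", "a", "b"], seed=0)

    def test_fixed_seed_reproduces_p(self, rng):
        d = self._clustered(rng)
        labels = ["a"] * 3 + ["b"] * 3
        p1 = mrpp(_dm(d), labels, seed=9).p_value
        p2 = mrpp(_dm(d), labels, seed=9).p_value
        assert p1 == p2


class TestPermanova:
    def test_null_data_large_p(self, rng):
        d = squareform(pdist(rng.random((12, 4))))
        labels = ["a", "b"] * 6
        res = permanova(_dm(d), labels, EcologyParams(n_permutations=499), seed=0)
        assert res.p_value > 0.05

    def test_perfect_separation_hits_floor(self, rng):
        pts = np.vstack([np.zeros((8, 2)), np.full((8, 2), 9.0)])
        pts += rng.normal(0, 1e-6, pts.shape)
        d = squareform(pdist(pts))
        res = permanova(_dm(d), ["a"] * 8 + ["b"] * 8,
                        EcologyParams(n_permutations=999), seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_ss_partition_matches_euclidean_centroids(self, rng):
        """For Euclidean distances the distance-based SS equals centroid SS."""
        pts = rng.random((6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d2 = squareform(pdist(pts)) ** 2
        f, r2 = _permanova_f(d2, labels)
        grand = pts.mean(axis=0)
        ss_total = ((pts - grand) ** 2).sum()
        ss_within = sum(
            ((pts[labels == g] - pts[labels == g].mean(axis=0)) ** 2).sum()
            for g in ("a", "b")
        )
        ss_between = ss_total - ss_within
        f_direct = (ss_between / 1) / (ss_within / 4)
        assert f == pytest.approx(f_direct)
        assert r2 == pytest.approx(ss_between / ss_total)

    def test_statistic_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix as SkbioDM

        d = squareform(pdist(rng.random((8, 3))))
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(_dm(d), labels, EcologyParams(n_permutations=99), seed=0)
        ref = skbio_stats.permanova(SkbioDM(d), grouping=labels, permutations=0)
        assert res.observed == pytest.approx(ref["test statistic"])


class TestBioenv:
    def test_planted_monotone_variable_wins(self, rng):
        pts = np.arange(8, dtype=float).reshape(-1, 1)
        d = _dm(squareform(pdist(pts)))
        env = pd.DataFrame(
            {"signal": np.arange(8, dtype=float),
             "noise": rng.random(8)},
            index=d.labels,
        )
        res = bioenv(d, env)
        assert res.best_subset == ("signal",)
        assert res.correlation > 0.95

    def test_reported_max_matches_brute_force(self, rng):
        d = _dm(squareform(pdist(rng.random((7, 3)))))
        env = pd.DataFrame(rng.random((7, 3)), columns=list("xyz"), index=d.labels)
        res = bioenv(d, env)
        target = rankdata(d.condensed())
        best = -np.inf
        for size in (1, 2, 3):
            for subset in itertools.combinations("xyz", size):
                z = (env[list(subset)] - env[list(subset)].mean()) / env[
                    list(subset)].std(ddof=1)
                rho = spearmanr(pdist(z.to_numpy()), target).statistic
                best = max(best, rho)
        assert res.correlation == pytest.approx(best)

    def test_constant_variable_dropped_with_warning(self, rng):
        d = _dm(squareform(pdist(rng.random((5, 2)))))
        env = pd.DataFrame(
            {"const": np.ones(5), "x": rng.random(5)}, index=d.labels
        )
        with pytest.warns(UserWarning, match="constant"):
            res = bioenv(d, env)
        assert res.best_subset == ("x",)


def exhaustive_mantel_p(x_dm, y_dm):
    n = len(x_dm)
    x = squareform(x_dm, checks=False)

    def corr(mat):
        y = squareform(mat, checks=False)
        xc, yc = x - x.mean(), y - y.mean()
        return (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())

    r_obs = corr(y_dm)
    rs = [
        corr(y_dm[np.ix_(perm, perm)])
        for perm in itertools.permutations(range(n))
    ]
    return sum(1 for r in rs if r >= r_obs - 1e-12) / len(rs)


class TestMantel:
    def test_identity_r_one_p_floor(self, rng):
        d = squareform(pdist(rng.random((8, 2))))
        res = mantel(_dm(d), _dm(d), EcologyParams(n_permutations=999), seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_affine_shift_invariance(self, rng):
        d = squareform(pdist(rng.random((6, 2))))
        shifted = d + 0.7
        np.fill_diagonal(shifted, 0.0)
        res = mantel(_dm(d), _dm(shifted), EcologyParams(n_permutations=99), seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_sampled_p_matches_exhaustive(self, rng):
        a = squareform(pdist(rng.random((5, 2))))
        b = squareform(pdist(rng.random((5, 2)) + 0.3 * rng.random((5, 2))))
        res = mantel(_dm(a), _dm(b), EcologyParams(n_permutations=999), seed=2)
        exact = exhaustive_mantel_p(a, b)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_r_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix as SkbioDM

        a = squareform(pdist(rng.random((7, 2))))
        b = squareform(pdist(rng.random((7, 2))))
        res = mantel(_dm(a), _dm(b), EcologyParams(n_permutations=99), seed=0)
        r_ref, _, _ = skbio_stats.mantel(
            SkbioDM(a), SkbioDM(b), method="pearson", permutations=0
        )
        assert res.observed == pytest.approx(r_ref)

    def test_mismatched_labels_rejected(self, rng):
        d = squareform(pdist(rng.random((4, 2))))
        with pytest.raises(ValueError, match="labels"):
            mantel(_dm(d), _dm(d, labels=list("wxyz")), seed=0)

    def test_zero_variance_rejected(self):
        flat = np.ones((4, 4)) - np.eye(4)
        d = squareform(pdist(np.random.default_rng(0).random((4, 2))))
        with pytest.raises(ValueError, match="variance"):
            mantel(_dm(flat), _dm(d), seed=0)
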