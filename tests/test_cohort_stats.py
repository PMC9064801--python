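import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import viroconverge as vc
from viroconverge.diversity_metrics import DistanceResult


def _dist(mat, ids):
    return DistanceResult(pd.DataFrame(mat, index=ids, columns=ids), metric="test")


def _euclidean_distresult(points, ids):
    from scipy.spatial.distance import pdist, squareform

    return _dist(squareform(pdist(points)), ids)


class TestPcoa:
    def test_collinear_points_recover_spacing(self):
        ids = ["a", "b", "c"]
        d = _dist([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids)
        res = vc.pcoa(d, k=1)
        x = res.coordinates["PC1"].to_numpy()
        # pairwise coordinate distances reproduce the inputs up to sign
        assert abs(x[0] - x[1]) == pytest.approx(1.0, abs=1e-9)
        assert abs(x[0] - x[2]) == pytest.approx(2.0, abs=1e-9)

    def test_planar_configuration_reconstructs_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        d = _euclidean_distresult(pts, ids)
        res = vc.pcoa(d, k=2)
        assert (res.eigenvalues > 1e-10).sum() == 2
        from scipy.spatial.distance import pdist

        rec = pdist(res.coordinates.to_numpy())
        np.testing.assert_allclose(rec, pdist(pts), atol=1e-9)

    def test_all_zero_distances_give_zero_coordinates(self):
        ids = ["a", "b", "c"]
        res = vc.pcoa(_dist(np.zeros((3, 3)), ids), k=2)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates.to_numpy(), 0)

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        ids = [f"s{i}" for i in range(10)]
        d = _euclidean_distresult(pts, ids)
        ours = vc.pcoa(d, k=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.matrix.to_numpy(), ids))
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.iloc[:, :3].to_numpy()),
            atol=1e-8,
        )


class TestPermanova:
    def test_two_clear_groups_exhaustive_minimum_p(self):
        """Two tight groups of 3: exhaustive enumeration gives the smallest
        attainable p, 2 of the 20 distinguishable assignments."""
        ids = [f"s{i}" for i in range(6)]
        mat = np.full((6, 6), 0.9)
        for i in range(6):
            mat[i, i] = 0.0
        for i, j in itertools.combinations(range(3), 2):
            mat[i, j] = mat[j, i] = 0.1
        for i, j in itertools.combinations(range(3, 6), 2):
            mat[i, j] = mat[j, i] = 0.1
        d = _dist(mat, ids)
        cov = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        res = vc.permanova(d, cov, exhaustive=True)
        assert res.p_value == pytest.approx(2 / 20)

    def test_observed_f_invariant_to_sample_relabelling(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 3))
        ids = [f"s{i}" for i in range(9)]
        d = _euclidean_distresult(pts, ids)
        cov = pd.Series(rng.normal(size=9), index=ids)
        f1 = vc.permanova(d, cov, permutations=99, seed=0).statistic
        perm = rng.permutation(9)
        d2 = _dist(d.matrix.to_numpy()[np.ix_(perm, perm)], [ids[i] for i in perm])
        f2 = vc.permanova(d2, cov[[ids[i] for i in perm]], permutations=99, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_constant_covariate_rejected(self):
        ids = ["a", "b", "c", "d"]
        d = _euclidean_distresult(np.random.default_rng(0).normal(size=(4, 2)), ids)
        with pytest.raises(ValueError, match="constant"):
            vc.permanova(d, pd.Series([1.0, 1.0, 1.0, 1.0], index=ids), permutations=99)

    def test_categorical_f_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        pts[6:] += 0.5
        ids = [f"s{i}" for i in range(12)]
        d = _euclidean_distresult(pts, ids)
        labels = ["a"] * 6 + ["b"] * 6
        ours = vc.permanova(d, pd.Series(labels, index=ids), permutations=99, seed=1)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.matrix.to_numpy(), ids), grouping=labels, permutations=99
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestWithinBetween:
    def test_constructed_matrix_exact(self):
        ids = ["i1a", "i1b", "i2a", "i2b"]
        samples = {
            "i1a": vc.SampleInfo("i1a", "i1", 1.0),
            "i1b": vc.SampleInfo("i1b", "i1", 2.0),
            "i2a": vc.SampleInfo("i2a", "i2", 1.0),
            "i2b": vc.SampleInfo("i2b", "i2", 2.0),
        }
        between = [0.88, 0.89, 0.91, 0.92]
        mat = np.zeros((4, 4))
        mat[0, 2], mat[0, 3], mat[1, 2], mat[1, 3] = between
        mat = mat + mat.T
        mat[0, 1] = mat[1, 0] = 0.08
        mat[2, 3] = mat[3, 2] = 0.12
        med_w, med_b, test = vc.within_between(_dist(mat, ids), samples)
        assert med_w == pytest.approx(0.1)
        assert med_b == pytest.approx(0.9)
        exact = st.mannwhitneyu([0.08, 0.12], between, alternative="two-sided", method="exact")
        assert test.p_value == pytest.approx(exact.pvalue)
        assert test.test_name == "mann_whitney_exact"

    def test_single_sample_per_infant_rejected(self):
        ids = ["a", "b"]
        samples = {
            "a": vc.SampleInfo("a", "i1", 1.0),
            "b": vc.SampleInfo("b", "i2", 1.0),
        }
        mat = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="within"):
            vc.within_between(_dist(mat, ids), samples)


class TestAlphaTrend:
    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(6)
        samples, alpha = {}, {}
        for i in range(20):
            intercept = rng.normal(2.0, 0.3)
            for k in range(6):
                dol = 3.0 + 9 * k
                sid = f"i{i}s{k}"
                samples[sid] = vc.SampleInfo(sid, f"i{i}", dol, pma_weeks=25 + dol / 7)
                alpha[sid] = intercept + 0.1 * (25 + dol / 7) + rng.normal(0, 0.05)
        slope, p = vc.alpha_trend(pd.Series(alpha), samples)
        assert slope == pytest.approx(0.1, rel=0.2)
        assert p < 0.001

    def test_constant_alpha_zero_slope(self):
        samples = {
            f"s{k}": vc.SampleInfo(f"s{k}", f"i{k%3}", 1.0 + k, pma_weeks=25 + (1.0 + k) / 7)
            for k in range(9)
        }
        slope, p = vc.alpha_trend(pd.Series({s: 1.5 for s in samples}), samples)
        assert slope == pytest.approx(0.0, abs=1e-8)

    def test_single_infant_falls_back_with_warning(self):
        samples = {
            f"s{k}": vc.SampleInfo(f"s{k}", "i1", 1.0 + k, pma_weeks=25 + (1.0 + k) / 7)
            for k in range(5)
        }
        alpha = pd.Series({f"s{k}": 1.0 + 0.2 * k for k in range(5)})
        with pytest.warns(UserWarning, match="single infant"):
            slope, _ = vc.alpha_trend(alpha, samples)
        assert slope == pytest.approx(0.2 * 7, rel=1e-6)  # per PMA week


class TestScalarTests:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 12], [4, 5]], 0.16),
            ([[5, 9], [6, 3]], 0.21),
        ],
    )
    def test_fisher_rounds_to_reported_value(self, table, expected):
        res = vc.fisher_exact_2x2(table)
        assert round(res.p_value, 2) == expected

    def test_fisher_milk_exposure_near_one(self):
        assert vc.fisher_exact_2x2([[13, 1], [8, 1]]).p_value > 0.99

    def test_fisher_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="margin"):
            res = vc.fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0

    def test_mann_whitney_exact_enumeration(self):
        res = vc.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.test_name == "mann_whitney_exact"

    def test_mann_whitney_identical_multisets(self):
        res = vc.mann_whitney([1.5, 2.5, 7.0], [7.0, 1.5, 2.5])
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_large_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(5, 1, 60)
        assert vc.mann_whitney(x, y).p_value < 1e-6
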