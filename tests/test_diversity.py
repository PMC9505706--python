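import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from taxrisk.diversity import (
    alpha_diversity,
    bray_curtis,
    pcoa,
    permanova,
    rarefy,
)
from taxrisk.errors import ConfigError, ValidationError

from tests._oracles import permanova_f_bruteforce


class TestRarefy:
    def test_rows_sum_exactly_to_depth(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 200, (10, 30)))
        out = rarefy(counts, depth=500, seed=1)
        assert (out.sum(axis=1) == 500).all()

    def test_full_depth_is_identity(self):
        counts = pd.DataFrame([[10, 5, 5]])
        out = rarefy(counts, depth=20, seed=0)
        assert out.iloc[0].tolist() == [10, 5, 5]

    def test_single_taxon_sample(self):
        out = rarefy(pd.DataFrame([[10, 0]]), depth=5, seed=0)
        assert out.iloc[0].tolist() == [5, 0]

    def test_shallow_samples_dropped_with_warning(self, caplog):
        counts = pd.DataFrame([[100, 100], [2, 1]], index=["deep", "shallow"])
        with caplog.at_level("WARNING"):
            out = rarefy(counts, depth=50, seed=0)
        assert list(out.index) == ["deep"]
        assert "dropping" in caplog.text

    def test_hypergeometric_mean(self):
        # taxon with 50 of 100 reads, depth 10 -> expected count 5
        counts = pd.DataFrame([[50, 50]])
        draws = [rarefy(counts, 10, seed=s).iloc[0, 0] for s in range(2000)]
        assert abs(np.mean(draws) - 5.0) < 0.2

    def test_reproducible_and_depth_validated(self):
        counts = pd.DataFrame([[40, 60]])
        a = rarefy(counts, 30, seed=9)
        b = rarefy(counts, 30, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ConfigError):
            rarefy(counts, 0)


class TestAlphaDiversity:
    def test_uniform_four_taxa(self):
        res = alpha_diversity(pd.DataFrame([[5, 5, 5, 5]]))
        row = res.values.iloc[0]
        assert row["simpson"] == pytest.approx(0.75)
        assert row["shannon"] == pytest.approx(np.log(4))
        assert row["observed"] == 4

    def test_single_taxon(self):
        row = alpha_diversity(pd.DataFrame([[9, 0]])).values.iloc[0]
        assert row["simpson"] == 0.0
        assert row["shannon"] == 0.0
        assert row["chao1"] == 1.0

    def test_chao1_formula(self):
        # S_obs=10, F1=4 singletons, F2=2 doubletons -> 10 + 16/4 = 14
        counts = [[5] * 4 + [1] * 4 + [2] * 2]
        row = alpha_diversity(pd.DataFrame(counts)).values.iloc[0]
        assert row["chao1"] == pytest.approx(14.0)
        assert row["chao1"] >= row["observed"]

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, 12)
        a = alpha_diversity(pd.DataFrame([counts])).values.iloc[0]
        b = alpha_diversity(pd.DataFrame([counts[::-1]])).values.iloc[0]
        for col in ("simpson", "shannon", "chao1", "observed"):
            assert a[col] == pytest.approx(b[col])

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValidationError):
            alpha_diversity(pd.DataFrame([[0, 0]]))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = bray_curtis(pd.DataFrame([[1, 2, 3], [1, 2, 3]]))
        assert dm[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(pd.DataFrame([[1, 0], [0, 1]]))
        assert dm[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        dm = bray_curtis(pd.DataFrame([[2, 2], [1, 3]]))
        assert dm[0, 1] == pytest.approx(0.25)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        dm = bray_curtis(pd.DataFrame(rng.random((6, 10))))
        mat = dm.data
        np.testing.assert_allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        assert mat.max() <= 1.0

    def test_two_all_zero_samples_error(self):
        with pytest.raises(ValidationError):
            bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 1]]))


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        ordn = pcoa(DistanceMatrix(D, ids=list("abcd")), n_axes=2)
        axis1 = ordn.coordinates.iloc[:, 0].to_numpy()
        # distances along axis 1 reproduce the input distances
        rec = np.abs(axis1[:, None] - axis1[None, :])
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        ordn = pcoa(DistanceMatrix(D, ids=list("abc")), n_axes=2)
        pos = ordn.eigenvalues[ordn.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_duplicated_samples_collapse(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        ordn = pcoa(DistanceMatrix(D, ids=list("abc")), n_axes=2)
        c = ordn.coordinates.to_numpy()
        np.testing.assert_allclose(c[0], c[1], atol=1e-8)

    def test_matches_skbio(self):
        rng = np.random.default_rng(4)
        dm = bray_curtis(pd.DataFrame(rng.random((8, 20))))
        ours = pcoa(dm, n_axes=3)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :ours.coordinates.shape[1]]),
            atol=1e-6)

    def test_too_many_axes_warns_and_truncates(self, caplog):
        D = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]).astype(float)
        with caplog.at_level("WARNING"):
            ordn = pcoa(DistanceMatrix(D, ids=list("abc")), n_axes=5)
        assert ordn.coordinates.shape[1] < 5
        assert sum(ordn.proportion_explained) <= 1 + 1e-12


class TestPermanova:
    @staticmethod
    def _clustered(n_per=5, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n_per, 3)),
                         rng.normal(sep, 1, (n_per, 3))])
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(pts)),
                              ids=[str(i) for i in range(2 * n_per)])

    def test_separated_clusters_minimal_p(self):
        # observed F is maximal: only a shuffle reproducing the exact
        # partition (probability 2/C(20,10) per draw) can tie it, so p sits
        # at the permutation floor up to such ties
        dm = self._clustered(n_per=10)
        labels = ["a"] * 10 + ["b"] * 10
        f, p = permanova(dm, labels, n_perm=199, seed=0)
        assert p <= 3 / 200
        assert f > 10

    def test_exhaustive_matches_bruteforce_distribution(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (6, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix(D, ids=[str(i) for i in range(6)])
        f_obs, p = permanova(dm, labels, n_perm="exact")
        # independent oracle: enumerate all 720 label permutations
        f_ref = permanova_f_bruteforce(D, labels)
        assert f_obs == pytest.approx(f_ref, rel=1e-10)
        fs = [permanova_f_bruteforce(D, labels[list(perm)])
              for perm in itertools.permutations(range(6))]
        p_ref = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_skbio(self):
        dm = self._clustered(n_per=6, sep=2.0, seed=3)
        labels = ["a"] * 6 + ["b"] * 6
        f_ours, _ = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, labels, permutations=99, seed=0)
        assert f_ours == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_group_of_one_errors(self):
        dm = self._clustered(n_per=3)
        with pytest.raises(ValidationError):
            permanova(dm, ["a"] * 5 + ["b"], n_perm=99)

    def test_null_type_one_error_calibrated(self):
        # i.i.d. labels: rejection rate at alpha=0.05 in [0.03, 0.07]
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            pts = rng.normal(0, 1, (16, 4))
            from scipy.spatial.distance import pdist, squareform
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[str(i) for i in range(16)])
            labels = rng.permutation(["a"] * 8 + ["b"] * 8)
            _, p = permanova(dm, labels, n_perm=99,
                             seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07
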