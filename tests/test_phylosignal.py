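import subprocess

import dendropy
import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import allotraj as at
from allotraj.phylosignal import tree_vcv


def _star_tree(s, length=1.0):
    tree = dendropy.Tree()
    tree.is_rooted = True
    for i in range(s):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        child.edge.length = length
        child.taxon = tree.taxon_namespace.new_taxon(label=f"T{i}")
    return tree


def _bm_traits(tree, species, rng, r=1):
    c = tree_vcv(tree, species)
    chol = np.linalg.cholesky(c)
    return chol @ rng.standard_normal((len(species), r))


def _univariate_k_oracle(y, c):
    """Independent univariate Blomberg K via eigendecomposition whitening."""
    n = len(y)
    eigval, q = np.linalg.eigh(c)
    w = q @ np.diag(1 / np.sqrt(eigval)) @ q.T     # C^{-1/2}
    ys, ones_s = w @ y, w @ np.ones(n)
    a = (ones_s @ ys) / (ones_s @ ones_s)
    mse0 = (y - a) @ (y - a)
    mse = (ys - ones_s * a) @ (ys - ones_s * a)
    c_inv_sum = float(np.ones(n) @ np.linalg.solve(c, np.ones(n)))
    expected = (np.trace(c) - n / c_inv_sum) / (n - 1)
    return (mse0 / mse) / expected


class TestPatristic:
    def test_tiny_tree_closed_form(self, tiny_tree):
        d = at.patristic_distances(tiny_tree, ["A", "B", "C"])
        np.testing.assert_allclose(
            d, [[0, 2, 4], [2, 0, 4], [4, 4, 0]], atol=1e-12
        )

    def test_ultrametric_tree_equidistant_through_root(self):
        tree = at.simulate_pure_birth_tree(8, seed=4)
        species = sorted(t.label for t in tree.taxon_namespace)
        c = tree_vcv(tree, species)
        d = at.patristic_distances(tree, species)
        # on an ultrametric tree, d_ij = depth_i + depth_j - 2*depth(mrca)
        depths = np.diag(c)
        oracle = depths[:, None] + depths[None, :] - 2 * c
        np.testing.assert_allclose(d, oracle, atol=1e-9)

    def test_matches_r_ape_cophenetic(self, tmp_path):
        tree = at.simulate_pure_birth_tree(7, seed=9)
        species = sorted(t.label for t in tree.taxon_namespace)
        nwk = tmp_path / "t.nwk"
        tree.write(path=str(nwk), schema="newick", suppress_rooting=True,
                   unquoted_underscores=True)
        script = (
            f'tr <- ape::read.tree("{nwk}"); d <- cophenetic(tr); '
            f'sp <- c({",".join(repr(s) for s in species)}); '
            f'write.csv(d[sp, sp], "{tmp_path}/d.csv")'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        import pandas as pd

        oracle = pd.read_csv(tmp_path / "d.csv", index_col=0).to_numpy()
        np.testing.assert_allclose(
            at.patristic_distances(tree, species), oracle, atol=1e-8
        )

    def test_missing_tip_rejected(self, tiny_tree):
        with pytest.raises(KeyError, match="Zzz"):
            at.patristic_distances(tiny_tree, ["A", "Zzz"])


class TestMatrixCorrelation:
    def test_affine_transform_gives_one(self, rng):
        m = squareform(rng.uniform(1, 9, size=10))
        assert at.matrix_correlation(m, 3.2 * m + 1.0) == pytest.approx(1.0, abs=1e-12)
        assert at.matrix_correlation(m, -m) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_triangle_oracle(self, rng):
        m1 = squareform(rng.uniform(0, 5, size=15))
        m2 = squareform(rng.uniform(0, 5, size=15))
        i, j = np.tril_indices(6, k=-1)
        oracle = stats.pearsonr(m1[i, j], m2[i, j]).statistic
        assert at.matrix_correlation(m1, m2) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        m = squareform([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero variance"):
            at.matrix_correlation(m, m)


class TestPCoA:
    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        mat = at.AngleMatrix(species=list("ABCD"), angles=d)
        res = at.pcoa_from_angles(mat)
        assert res.coordinates.shape[1] == 1
        got = np.sort(res.coordinates[:, 0] - res.coordinates[:, 0].min())
        np.testing.assert_allclose(got, x, atol=1e-9)

    def test_distances_reconstructed_when_euclidean(self, rng):
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = at.pcoa_from_angles(at.AngleMatrix(species=[f"S{i}" for i in range(6)], angles=d))
        np.testing.assert_allclose(squareform(pdist(res.coordinates)), d, atol=1e-6)

    def test_eigenvalues_match_skbio(self, six_species_result):
        skbio = pytest.importorskip("skbio")
        mat = six_species_result.angle_matrix
        res = at.pcoa_from_angles(mat)
        dm = skbio.DistanceMatrix(mat.angles, ids=mat.species)
        oracle = skbio.stats.ordination.pcoa(dm, method="eigh")
        oracle_pos = np.sort(oracle.eigvals[oracle.eigvals > 1e-8 * oracle.eigvals.max()])
        np.testing.assert_allclose(np.sort(res.eigenvalues), oracle_pos, rtol=1e-8)

    def test_all_zero_rejected(self):
        mat = at.AngleMatrix(species=list("ABC"), angles=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no variation"):
            at.pcoa_from_angles(mat)


class TestKmult:
    def test_univariate_matches_whitening_oracle(self, rng):
        tree = at.simulate_pure_birth_tree(10, seed=2)
        species = sorted(t.label for t in tree.taxon_namespace)
        y = _bm_traits(tree, species, rng)[:, 0]
        res = at.kmult(y, tree, species, n_permutations=9, seed=0)
        oracle = _univariate_k_oracle(y, tree_vcv(tree, species))
        assert res.k_stat == pytest.approx(oracle, abs=1e-9)

    def test_univariate_matches_picante(self, tmp_path, rng):
        tree = at.simulate_pure_birth_tree(8, seed=5)
        species = sorted(t.label for t in tree.taxon_namespace)
        y = _bm_traits(tree, species, rng)[:, 0]
        nwk = tmp_path / "t.nwk"
        tree.write(path=str(nwk), schema="newick", suppress_rooting=True,
                   unquoted_underscores=True)
        traits = ",".join(f"{s}={float(v)!r}" for s, v in zip(species, y))
        script = (
            "suppressMessages(library(picante)); "
            f'tr <- ape::read.tree("{nwk}"); '
            f"x <- c({traits}); "
            'cat(sprintf("%.15e", Kcalc(x[tr$tip.label], tr)))'
        )
        out = subprocess.run(["Rscript", "-e", script], check=True,
                             capture_output=True, text=True)
        oracle = float(out.stdout.strip().split()[-1])
        res = at.kmult(y, tree, species, n_permutations=9, seed=0)
        assert res.k_stat == pytest.approx(oracle, abs=1e-9)

    def test_star_tree_equal_lengths_k_is_one(self, rng):
        tree = _star_tree(9)
        species = [f"T{i}" for i in range(9)]
        y = rng.standard_normal((9, 3))
        res = at.kmult(y, tree, species, n_permutations=9, seed=0)
        assert res.k_stat == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_trait_rotation(self, rng):
        tree = at.simulate_pure_birth_tree(12, seed=8)
        species = sorted(t.label for t in tree.taxon_namespace)
        y = _bm_traits(tree, species, rng, r=5)
        q = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        k1 = at.kmult(y, tree, species, n_permutations=9, seed=0).k_stat
        k2 = at.kmult(y @ q, tree, species, n_permutations=9, seed=0).k_stat
        assert k1 == pytest.approx(k2, abs=1e-9)

    def test_permutation_p_reproducible(self, rng):
        tree = at.simulate_pure_birth_tree(10, seed=3)
        species = sorted(t.label for t in tree.taxon_namespace)
        y = _bm_traits(tree, species, rng, r=2)
        r1 = at.kmult(y, tree, species, n_permutations=199, seed=42)
        r2 = at.kmult(y, tree, species, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 200

    def test_null_p_values_uniform(self):
        # permutation p-values are discrete (multiples of 1/100), so test
        # uniformity with a chi-square over bins that align with the support
        tree = at.simulate_pure_birth_tree(10, seed=6)
        species = sorted(t.label for t in tree.taxon_namespace)
        rng = np.random.default_rng(99)
        pvals = np.array([
            at.kmult(rng.standard_normal((10, 2)), tree, species,
                     n_permutations=99, seed=int(rng.integers(2**31))).p_value
            for _ in range(200)
        ])
        counts = np.histogram(pvals, bins=np.linspace(0.005, 1.005, 11))[0]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_too_few_species_rejected(self, tiny_tree):
        with pytest.raises(ValueError, match="at least 4"):
            at.kmult(np.zeros((3, 2)), tiny_tree, ["A", "B", "C"])


class TestMeanShapeSignal:
    def test_distance_matrix_matches_procrustes_oracle(self, six_species_result):
        res = six_species_result
        sig = res.signal["mean_shape"]
        labels = np.asarray(res.dataset.species)
        for i, si in enumerate(sig.species):
            for j, sj in enumerate(sig.species):
                if i < j:
                    mi = res.aligned.aligned[labels == si].mean(axis=0)
                    mj = res.aligned.aligned[labels == sj].mean(axis=0)
                    assert sig.distance_matrix[i, j] == pytest.approx(
                        at.procrustes_distance(mi, mj), abs=1e-9
                    )

    def test_brownian_means_k_near_one(self):
        """Species means evolved by BM with small within-species noise give K ~ 1."""
        ks = []
        for seed in range(30):
            tree = at.simulate_pure_birth_tree(12, seed=777)
            species = sorted(t.label for t in tree.taxon_namespace)
            rng = np.random.default_rng(seed)
            means = _bm_traits(tree, species, rng, r=4)
            noisy = means + rng.normal(0, 0.02, size=means.shape)
            ks.append(at.kmult(noisy, tree, species, n_permutations=9, seed=0).k_stat)
        assert abs(np.mean(ks) - 1.0) < 0.15

    def test_identical_means_rejected(self, six_species_result):
        res = six_species_result
        flat = np.zeros_like(res.aligned.aligned) + res.aligned.mean_shape
        with pytest.raises(ValueError, match="identical"):
            at.mean_shape_signal(
                flat, np.zeros_like(res.scores.scores),
                res.dataset.species, _star_tree(6), at.StudyConfig(),
            )
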