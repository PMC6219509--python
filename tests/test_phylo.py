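import itertools

import numpy as np
import pytest

from traitspace.io import phylogeny_from_newick
from traitspace.phylo import (
    abouheif_proximity,
    moran_cmean,
    multivariate_moran,
    phylo_eigenvectors,
    phylo_residuals,
    select_eigenvectors,
    test_signal as run_signal_test,
    test_signal_multivariate as run_multivariate_signal_test,
)
from traitspace.simulate import simulate_traits_bm, simulate_yule_tree


class TestAbouheifProximity:
    def test_star_tree_uniform(self, star_tree):
        prox = abouheif_proximity(star_tree)
        n = 5
        off = prox.A[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 1 / n)
        assert np.allclose(np.diag(prox.A), 0)

    def test_balanced_tree_hand_enumeration(self, balanced_tree):
        # path A-B crosses one node with 2 children: 1/2
        # path A-C crosses three nodes, each with 2 children: 1/8
        prox = abouheif_proximity(balanced_tree)
        order = {t: i for i, t in enumerate(prox.tip_order)}
        assert prox.A[order["A"], order["B"]] == pytest.approx(0.5)
        assert prox.A[order["A"], order["C"]] == pytest.approx(0.125)
        assert prox.A[order["C"], order["D"]] == pytest.approx(0.5)

    def test_polytomy_child_counts(self):
        # path A-B crosses only the root with 3 direct descendants
        prox = abouheif_proximity(phylogeny_from_newick("(A,B,(C,D));"))
        order = {t: i for i, t in enumerate(prox.tip_order)}
        assert prox.A[order["A"], order["B"]] == pytest.approx(1 / 3)
        assert prox.A[order["C"], order["D"]] == pytest.approx(1 / 2)
        assert prox.A[order["A"], order["C"]] == pytest.approx(1 / 6)

    def test_topology_only_branch_lengths_ignored(self):
        with_bl = abouheif_proximity(
            phylogeny_from_newick("((A:0.0,B:9):1,(C:2,D:3):0.0);")
        )
        without = abouheif_proximity(phylogeny_from_newick("((A,B),(C,D));"))
        assert np.allclose(with_bl.A, without.A)

    def test_symmetry_and_row_standardization(self, rng):
        tree = simulate_yule_tree(40, rng)
        prox = abouheif_proximity(tree)
        assert np.allclose(prox.A, prox.A.T)
        assert np.allclose(prox.W.sum(axis=1), 1.0)
        off = prox.A[~np.eye(40, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            abouheif_proximity(phylogeny_from_newick("(A,B);"))


class TestMoranCmean:
    def test_star_tree_closed_form(self, star_tree, rng):
        prox = abouheif_proximity(star_tree)
        values = rng.normal(size=5)
        assert moran_cmean(values, prox.W) == pytest.approx(-1 / 4, abs=1e-10)

    def test_clade_structured_values_positive(self, balanced_tree):
        prox = abouheif_proximity(balanced_tree)
        values = np.array(
            [10.0 if t in ("A", "B") else -10.0 for t in prox.tip_order]
        )
        assert moran_cmean(values, prox.W) > 0

    def test_constant_vector_rejected(self, star_tree):
        prox = abouheif_proximity(star_tree)
        with pytest.raises(ValueError, match="constant"):
            moran_cmean(np.ones(5), prox.W)

    def test_white_noise_near_zero_on_large_tree(self, rng):
        tree = simulate_yule_tree(200, rng)
        W = abouheif_proximity(tree).W
        hits = sum(
            abs(moran_cmean(rng.normal(size=200), W)) < 0.1 for _ in range(40)
        )
        assert hits >= 38


class TestSignalTest:
    def test_matches_exhaustive_enumeration_small_tree(self, rng):
        phy = phylogeny_from_newick("(((A,B),(C,D)),(E,F));")
        prox = abouheif_proximity(phy)
        values = np.array([3.1, 2.9, 1.0, 1.2, -2.0, -1.7])
        obs = moran_cmean(values, prox.W)
        exact_null = [
            moran_cmean(np.array(p), prox.W)
            for p in itertools.permutations(values)
        ]
        p_exact = np.mean(np.array(exact_null) >= obs)
        res = run_signal_test(values, prox.W, n_perm=999, seed=1)
        assert res.p == pytest.approx(p_exact, abs=0.05)

    def test_same_seed_same_result(self, rng):
        tree = simulate_yule_tree(30, rng)
        W = abouheif_proximity(tree).W
        v = rng.normal(size=30)
        a = run_signal_test(v, W, seed=42)
        b = run_signal_test(v, W, seed=42)
        assert a.p == b.p
        assert np.array_equal(a.null, b.null)

    def test_brownian_traits_detected(self):
        hits = 0
        n_sims = 30
        for i in range(n_sims):
            tree = simulate_yule_tree(100, seed=1000 + i)
            traits = simulate_traits_bm(
                tree, np.zeros(3), np.diag([0.06, 0.25, 0.6]), seed=i
            )
            prox = abouheif_proximity(tree)
            vals = traits.loc[list(prox.tip_order), "height_max"].to_numpy()
            hits += run_signal_test(vals, prox.W, n_perm=199, seed=i).p <= 0.05
        assert hits >= int(0.9 * n_sims)


class TestPhyloEigenvectors:
    def test_columns_centered_and_orthonormal(self, rng):
        tree = simulate_yule_tree(50, rng)
        prox = abouheif_proximity(tree)
        eig = phylo_eigenvectors(prox)
        assert np.all(np.abs(eig.vectors.sum(axis=0)) < 1e-8)
        gram = eig.vectors.T @ eig.vectors
        assert np.allclose(gram, np.eye(eig.m), atol=1e-8)
        assert np.all(np.diff(eig.eigenvalues) <= 1e-12)

    def test_spectral_reconstruction(self, balanced_tree):
        prox = abouheif_proximity(balanced_tree)
        n = prox.n
        H = np.eye(n) - np.full((n, n), 1 / n)
        B = H @ prox.A @ H
        vals, vecs = np.linalg.eigh((B + B.T) / 2)
        assert np.allclose(vecs @ np.diag(vals) @ vecs.T, B, atol=1e-8)
        eig = phylo_eigenvectors(prox)
        recon = eig.vectors @ np.diag(eig.eigenvalues) @ eig.vectors.T
        # positive part reproduces B up to its negative/null spectrum
        resid = B - recon
        assert np.all(np.linalg.eigvalsh((resid + resid.T) / 2) <= 1e-8)

    def test_star_tree_degenerate_spectrum(self, star_tree):
        eig = phylo_eigenvectors(abouheif_proximity(star_tree))
        if eig.m:
            assert np.allclose(eig.eigenvalues, eig.eigenvalues[0])


class TestMultivariateMoran:
    def test_identical_columns_collapse_to_univariate(self, balanced_tree, rng):
        W = abouheif_proximity(balanced_tree).W
        v = rng.normal(size=4)
        X = np.column_stack([v, v, v])
        assert multivariate_moran(X, W) == pytest.approx(moran_cmean(v, W))

    def test_z_scored_columns_equal_plain_mean(self, rng):
        tree = simulate_yule_tree(30, rng)
        W = abouheif_proximity(tree).W
        X = rng.normal(size=(30, 3))
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        expected = np.mean([moran_cmean(Xz[:, j], W) for j in range(3)])
        assert multivariate_moran(Xz, W) == pytest.approx(expected)

    def test_inertia_weighting_on_scaled_columns(self, rng):
        tree = simulate_yule_tree(25, rng)
        W = abouheif_proximity(tree).W
        X = rng.normal(size=(25, 3))
        scaled = X * np.array([1.0, 2.0, 3.0])
        Xc = scaled - scaled.mean(0)
        ss = (Xc ** 2).sum(0)
        expected = sum(
            ss[j] * moran_cmean(Xc[:, j], W) for j in range(3)
        ) / ss.sum()
        assert multivariate_moran(scaled, W) == pytest.approx(expected)

    def test_constant_column_rejected(self, star_tree, rng):
        W = abouheif_proximity(star_tree).W
        X = np.column_stack([rng.normal(size=5), np.ones(5), rng.normal(size=5)])
        with pytest.raises(ValueError):
            multivariate_moran(X, W)

    def test_row_permutation_test_deterministic(self, rng):
        tree = simulate_yule_tree(30, rng)
        W = abouheif_proximity(tree).W
        X = rng.normal(size=(30, 3))
        a = run_multivariate_signal_test(X, W, n_perm=199, seed=5)
        b = run_multivariate_signal_test(X, W, n_perm=199, seed=5)
        assert a.p == b.p and np.array_equal(a.null, b.null)


@pytest.fixture(scope="module")
def setup():
    tree = simulate_yule_tree(60, seed=77)
    prox = abouheif_proximity(tree)
    return prox, phylo_eigenvectors(prox)


class TestEigenvectorSelection:

    def test_no_signal_selects_nothing(self, setup, rng):
        prox, eig = setup
        target = rng.normal(size=60)
        sel = select_eigenvectors(target, eig, prox.W, seed=1)
        if sel.p_trajectory[0] > 0.05:
            assert sel.selected == ()

    def test_planted_eigenvector_recovered(self, setup, rng):
        prox, eig = setup
        target = 5 * eig.vectors[:, 0] + 0.02 * rng.normal(size=60)
        sel = select_eigenvectors(target, eig, prox.W, seed=2)
        assert sel.selected == (0,)
        assert sel.final_p > 0.05

    def test_trajectory_monotone_when_steps_taken(self, setup):
        prox, eig = setup
        rng = np.random.default_rng(9)
        target = (
            3 * eig.vectors[:, 0] + 2 * eig.vectors[:, 2]
            + 0.05 * rng.normal(size=60)
        )
        sel = select_eigenvectors(target, eig, prox.W, seed=3)
        assert all(np.diff(sel.trajectory) <= 1e-12)

    def test_max_k_beyond_m_rejected(self, setup, rng):
        prox, eig = setup
        with pytest.raises(ValueError):
            select_eigenvectors(
                rng.normal(size=60), eig, prox.W, max_k=eig.m + 1, seed=0
            )


class TestPhyloResiduals:
    def test_empty_selection_centers_target(self, setup_tree=None):
        tree = simulate_yule_tree(20, seed=3)
        prox = abouheif_proximity(tree)
        eig = phylo_eigenvectors(prox)
        rng = np.random.default_rng(0)
        target = rng.normal(size=20) + 5
        sel = select_eigenvectors(target, eig, prox.W, seed=1, n_perm=99)
        if not sel.selected:
            resid = phylo_residuals(target, sel, eig)
            assert np.allclose(resid, target - target.mean())

    def test_residuals_orthogonal_and_contracted(self):
        tree = simulate_yule_tree(40, seed=11)
        prox = abouheif_proximity(tree)
        eig = phylo_eigenvectors(prox)
        rng = np.random.default_rng(1)
        target = 4 * eig.vectors[:, 1] + rng.normal(size=40)
        sel = select_eigenvectors(target, eig, prox.W, seed=4, n_perm=199)
        resid = phylo_residuals(target, sel, eig)
        for j in sel.selected:
            assert abs(resid @ eig.vectors[:, j]) < 1e-8
        assert resid.var() <= target.var() + 1e-12
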