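"""Phylogenetic autocorrelation and eigenvector-based phylogenetic correction.

Phylogenetic signal — the tendency of closely related species to carry
similar trait values — is measured with Abouheif's C_mean, a Moran's-I-type
statistic built on a topology-only proximity matrix: the proximity of two
tips is the product, over the internal nodes on the path between them, of
1 / (number of direct descendants of the node). Significance comes from
randomizing trait values across tips.

Phylogenetic correction uses eigenvector regression: the double-centered
proximity matrix is eigendecomposed, and eigenvectors are greedily added to
an OLS model of the trait until the residual autocorrelation is no longer
significant ("best performing" selection). Residuals of that model are the
phylogeny-free trait values used by downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Phylogeny

__all__ = [
    "ProximityMatrix",
    "PhyloEigenvectors",
    "SignalTestResult",
    "EigenvectorSelection",
    "abouheif_proximity",
    "moran_cmean",
    "multivariate_moran",
    "test_signal",
    "test_signal_multivariate",
    "phylo_eigenvectors",
    "select_eigenvectors",
    "phylo_residuals",
]


@dataclass(frozen=True)
class ProximityMatrix:
    """Abouheif proximities ``A`` and their row-standardized weight form ``W``."""

    A: np.ndarray
    W: np.ndarray
    tip_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.tip_order)


@dataclass(frozen=True)
class PhyloEigenvectors:
    """Positive-eigenvalue part of the double-centered proximity matrix."""

    eigenvalues: np.ndarray  # descending, all > 0
    vectors: np.ndarray      # n x m, orthonormal columns, each summing to ~0
    tip_order: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class SignalTestResult:
    statistic: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class EigenvectorSelection:
    selected: tuple[int, ...]          # eigenvector column indices, in order chosen
    trajectory: tuple[float, ...]      # residual statistic after 0,1,... additions
    p_trajectory: tuple[float, ...]
    final_p: float
    alpha: float
    stopped_by_max_k: bool


def abouheif_proximity(phylogeny: Phylogeny) -> ProximityMatrix:
    """Topology-only Abouheif proximity matrix for the tips of a rooted tree.

    For tips i != j, ``A[i, j]`` is the product over all internal nodes on
    the path from i to j of 1/(number of direct descendants of the node);
    branch lengths are ignored, and polytomies are handled natively (a node
    may have any number of children). ``W`` divides each row of ``A`` by its
    row sum, the weight form used by the Moran-type statistics.
    """
    tree = phylogeny.tree
    tips = list(tree.leaf_node_iter())
    n = len(tips)
    if n < 3:
        raise ValueError("Abouheif proximity requires at least 3 tips")
    index = {id(leaf): i for i, leaf in enumerate(tips)}
    tip_order = tuple(leaf.taxon.label for leaf in tips)

    A = np.zeros((n, n))
    # Postorder merge: for node v, carry (tip index, product of 1/dd over the
    # internal nodes strictly between the tip and v) for each tip below v.
    stack: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stack[id(node)] = (np.array([index[id(node)]]), np.ones(1))
            continue
        children = node.child_nodes()
        dd = len(children)
        parts = [stack.pop(id(c)) for c in children]
        for a in range(len(parts)):
            ia, pa = parts[a]
            for b in range(a + 1, len(parts)):
                ib, pb = parts[b]
                block = (pa[:, None] * pb[None, :]) / dd
                A[np.ix_(ia, ib)] = block
                A[np.ix_(ib, ia)] = block.T
        idx = np.concatenate([p[0] for p in parts])
        prod = np.concatenate([p[1] for p in parts]) / dd
        stack[id(node)] = (idx, prod)

    W = A / A.sum(axis=1, keepdims=True)
    return ProximityMatrix(A=A, W=W, tip_order=tip_order)


def _center(values: np.ndarray, what: str) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if z.ndim != 1:
        raise ValueError(f"{what} must be a vector")
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{what} contains non-finite values")
    z = z - z.mean()
    if np.allclose(z, 0):
        raise ValueError(f"{what} is constant; statistic undefined")
    return z


def moran_cmean(values: np.ndarray, W: np.ndarray) -> float:
    """Abouheif's C_mean: Moran's I of ``values`` under row-standardized
    Abouheif weights ``W`` (rows summing to 1, so the usual n/S0 factor is 1)."""
    z = _center(values, "values")
    return float(z @ W @ z / (z @ z))


def multivariate_moran(X: np.ndarray, W: np.ndarray) -> float:
    """Inertia-weighted mean of per-column Moran statistics.

    Each column's Moran form is weighted by its sum of squares, so the
    statistic equals trace(Xc' W Xc) / trace(Xc' Xc) for the column-centered
    matrix Xc; for z-scored columns this collapses to the plain mean of the
    univariate statistics.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    Xc = X - X.mean(axis=0)
    ss = (Xc ** 2).sum(axis=0)
    if np.any(np.isclose(ss, 0)):
        raise ValueError("constant column; statistic undefined")
    num = float(np.einsum("ij,ik,kj->", Xc, W, Xc))
    return num / float(ss.sum())


def _perm_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _one_sided_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def test_signal(
    values: np.ndarray,
    W: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> SignalTestResult:
    """Permutation test of C_mean, one-sided toward positive autocorrelation.

    Null replicates permute the trait values uniformly across tips;
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    z = _center(values, "values")
    rng = np.random.default_rng(seed)
    obs = float(z @ W @ z / (z @ z))
    P = _perm_indices(rng, n_perm, len(z))
    Zp = z[P]
    null = np.einsum("bi,ij,bj->b", Zp, W, Zp) / (z @ z)
    return SignalTestResult(
        statistic=obs,
        null=null,
        p=_one_sided_p(null, obs),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )


def test_signal_multivariate(
    X: np.ndarray,
    W: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> SignalTestResult:
    """Permutation test of the multivariate Moran statistic.

    Each replicate permutes whole rows of X jointly, preserving the
    cross-trait correlation structure under the null.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    ss = (Xc ** 2).sum(axis=0)
    if np.any(np.isclose(ss, 0)):
        raise ValueError("constant column; statistic undefined")
    den = float(ss.sum())
    rng = np.random.default_rng(seed)
    obs = float(np.einsum("ij,ik,kj->", Xc, W, Xc)) / den
    P = _perm_indices(rng, n_perm, X.shape[0])
    null = np.zeros(n_perm)
    for j in range(Xc.shape[1]):
        Zp = Xc[:, j][P]
        null += np.einsum("bi,ij,bj->b", Zp, W, Zp)
    null /= den
    return SignalTestResult(
        statistic=obs,
        null=null,
        p=_one_sided_p(null, obs),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )


def phylo_eigenvectors(prox: ProximityMatrix, tol: float = 1e-10) -> PhyloEigenvectors:
    """Eigenvectors of the double-centered Abouheif proximity matrix.

    B = H A H with H = I - 11'/n is eigendecomposed; columns with eigenvalue
    above ``tol`` are kept, ordered by descending eigenvalue. Because B
    annihilates the constant vector, every kept eigenvector sums to ~0.
    """
    A = prox.A
    n = A.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    B = H @ A @ H
    B = (B + B.T) / 2
    eigenvalues, vectors = np.linalg.eigh(B)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    keep = eigenvalues > tol
    return PhyloEigenvectors(
        eigenvalues=eigenvalues[keep],
        vectors=vectors[:, keep],
        tip_order=prox.tip_order,
    )


def _ols_residuals(
    target: np.ndarray, columns: np.ndarray | None
) -> np.ndarray:
    """Residuals of OLS of target on [intercept, columns]."""
    target = np.asarray(target, dtype=float)
    n = target.shape[0]
    if columns is None or columns.size == 0:
        return target - target.mean(axis=0)
    D = np.column_stack([np.ones(n), columns])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(D, target, rcond=None)
    return target - D @ beta


def select_eigenvectors(
    target: np.ndarray,
    eig: PhyloEigenvectors,
    W: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    max_k: int | None = None,
) -> EigenvectorSelection:
    """Greedy ("best performing") eigenvector selection.

    At each step every unselected eigenvector is tried as an addition to the
    OLS model of the target; the one minimizing the residual autocorrelation
    statistic (C_mean for vector targets, the multivariate Moran statistic
    for matrix targets) is kept. The search stops as soon as the permutation
    test on the residuals is nonsignificant (p > alpha), or when ``max_k``
    eigenvectors have been taken (flagged). A target whose initial signal
    test is already nonsignificant selects nothing.
    """
    target = np.asarray(target, dtype=float)
    multivariate = target.ndim == 2
    n, m = eig.vectors.shape
    if max_k is None:
        max_k = min(m, n // 2)
    if max_k > m:
        raise ValueError(f"max_k={max_k} exceeds the {m} available eigenvectors")
    stat = multivariate_moran if multivariate else moran_cmean
    test = test_signal_multivariate if multivariate else test_signal
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    resid = _ols_residuals(target, None)
    trajectory = [stat(resid, W)]
    result = test(resid, W, n_perm=n_perm, seed=rng)
    p_trajectory = [result.p]
    stopped_by_max_k = False

    while result.p <= alpha:
        if len(selected) == max_k:
            stopped_by_max_k = True
            break
        candidates = [j for j in range(m) if j not in selected]
        best_j, best_stat, best_resid = None, np.inf, None
        for j in candidates:
            cols = eig.vectors[:, selected + [j]]
            r = _ols_residuals(target, cols)
            s = stat(r, W)
            if s < best_stat:
                best_j, best_stat, best_resid = j, s, r
        selected.append(best_j)
        resid = best_resid
        trajectory.append(best_stat)
        result = test(resid, W, n_perm=n_perm, seed=rng)
        p_trajectory.append(result.p)

    return EigenvectorSelection(
        selected=tuple(selected),
        trajectory=tuple(trajectory),
        p_trajectory=tuple(p_trajectory),
        final_p=result.p,
        alpha=alpha,
        stopped_by_max_k=stopped_by_max_k,
    )


def phylo_residuals(
    target: np.ndarray,
    selection: EigenvectorSelection,
    eig: PhyloEigenvectors,
) -> np.ndarray:
    """OLS residuals of the target on the selected eigenvectors (+ intercept).

    An empty selection returns the mean-centered target (intercept-only fit).
    """
    cols = eig.vectors[:, list(selection.selected)] if selection.selected else None
    return _ols_residuals(target, cols)
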