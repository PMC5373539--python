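"""Phylogenetic signal machinery: Blomberg's K, patristic distances, Mantel tests.

Blomberg's K compares the variance of a tip trait to the variance expected if
the trait had evolved by Brownian motion (BM) along the tree.  Writing ``V``
for the tree's variance-covariance matrix (shared root-to-tip path lengths),
``x`` for the trait vector over ``n`` tips and ``1`` for a vector of ones:

    a_hat  = (1' V^-1 x) / (1' V^-1 1)          phylogenetic mean
    MSE0   = (x - a_hat 1)'        (x - a_hat 1) / (n - 1)
    MSE    = (x - a_hat 1)' V^-1   (x - a_hat 1) / (n - 1)
    E[MSE0/MSE] = [tr(V) - n / (1' V^-1 1)] / (n - 1)
    K      = (MSE0 / MSE) / E[MSE0/MSE]

K ~ 1 under BM, K -> 0 when close relatives are no more similar than random
tips.  Significance is assessed by permuting trait values across tips: the
permutation statistic is the observed MSE0/MSE ratio, which is equivalent to
permuting K itself because the BM expectation term is permutation invariant.

The Mantel test correlates the lower triangles of two distance matrices and
builds its null by simultaneously permuting the rows and columns of one
matrix.  Both tests use the add-one p-value convention
``p = (1 + #{null >= observed}) / (1 + n_perm)`` so p is never exactly zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

PhyloTree = dendropy.Tree

__all__ = [
    "PhyloTree",
    "KResult",
    "MantelResult",
    "vcv_from_tree",
    "patristic_distances",
    "blomberg_k",
    "k_permutation_test",
    "trait_distance_matrix",
    "mantel",
]


@dataclass(frozen=True)
class KResult:
    """Blomberg's K with (optionally) a permutation p-value."""

    k: float
    observed_ratio: float
    expected_ratio: float
    p: float | None
    n_perm: int
    seed: int | None
    n_tips_used: int


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    p: float | None
    n_perm: int
    seed: int | None
    n_labels: int


def _tip_labels(tree: PhyloTree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate tip labels")
    return labels


def vcv_from_tree(tree: PhyloTree, zero_length_epsilon: float = 1e-8) -> pd.DataFrame:
    """Tip-by-tip matrix of shared root-to-tip path lengths.

    Diagonal entries are root-to-tip distances; off-diagonal entries are the
    depth of the pair's most recent common ancestor.  This is the trait
    covariance structure implied by Brownian motion on the tree (up to the
    diffusion rate).  Tips on zero-length pendant edges get
    ``zero_length_epsilon`` added to their diagonal so the matrix stays
    invertible.
    """
    labels = _tip_labels(tree)
    index = {}
    n = len(labels)
    V = np.zeros((n, n))

    depth: dict[int, float] = {}
    leafsets: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0  # any root edge length is not part of the tree depth
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    if max(depth.values()) <= 0.0:
        raise ValueError("tree has zero total depth")

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = len(index)
            index[node.taxon.label] = i
            V[i, i] = depth[id(node)]
            if (node.edge.length or 0.0) == 0.0:
                V[i, i] += zero_length_epsilon
            leafsets[id(node)] = [i]
        else:
            children = node.child_nodes()
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in leafsets[id(children[a])]:
                        for j in leafsets[id(children[b])]:
                            V[i, j] = V[j, i] = d
            leafsets[id(node)] = [i for c in children for i in leafsets[id(c)]]

    order = [index[lab] for lab in labels]
    V = V[np.ix_(order, order)]
    return pd.DataFrame(V, index=labels, columns=labels)


def patristic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix.

    Uses the identity d(i, j) = V[i,i] + V[j,j] - 2 V[i,j], which holds for
    any rooted tree with nonnegative branch lengths.
    """
    V = vcv_from_tree(tree, zero_length_epsilon=0.0)
    v = np.diag(V.to_numpy())
    D = v[:, None] + v[None, :] - 2.0 * V.to_numpy()
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=V.index, columns=V.columns)


def _align_traits(tree: PhyloTree, traits: Mapping[str, float] | pd.Series,
                  zero_length_epsilon: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Subset the tree VCV to tips with non-missing trait values.

    Restricting the VCV to a tip subset equals the VCV of the pruned tree, so
    missing-trait tips are handled without tree surgery.
    """
    series = pd.Series(traits, dtype=float)
    V = vcv_from_tree(tree, zero_length_epsilon=zero_length_epsilon)
    keep = [lab for lab in V.index if lab in series.index and np.isfinite(series[lab])]
    if len(keep) < 3:
        raise ValueError(f"need trait values for >= 3 tips, have {len(keep)}")
    x = series[keep].to_numpy()
    if np.ptp(x) == 0.0:
        raise ValueError("trait vector has zero variance")
    return V.loc[keep, keep].to_numpy(), x, keep


def _k_ingredients(V: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("tree VCV matrix is singular") from exc
    one = np.ones(V.shape[0])
    u = Vinv @ one
    s = float(one @ u)
    n = V.shape[0]
    expected_ratio = (np.trace(V) - n / s) / (n - 1)
    return Vinv, u, s, expected_ratio


def _mse_ratio(X: np.ndarray, Vinv: np.ndarray, u: np.ndarray, s: float) -> np.ndarray:
    """MSE0/MSE for each row of a (m, n) matrix of trait vectors."""
    a_hat = X @ u / s
    R = X - a_hat[:, None]
    mse0 = np.einsum("pi,pi->p", R, R)
    mse = np.einsum("pi,ij,pj->p", R, Vinv, R)
    return mse0 / mse


def blomberg_k(tree: PhyloTree, traits: Mapping[str, float] | pd.Series,
               zero_length_epsilon: float = 1e-8) -> KResult:
    """Blomberg's K statistic (no permutation test; ``p`` is None).

    Tips with missing trait values are dropped and the tree implicitly pruned.
    """
    V, x, keep = _align_traits(tree, traits, zero_length_epsilon)
    Vinv, u, s, expected = _k_ingredients(V)
    ratio = float(_mse_ratio(x[None, :], Vinv, u, s)[0])
    return KResult(k=ratio / expected, observed_ratio=ratio, expected_ratio=expected,
                   p=None, n_perm=0, seed=None, n_tips_used=len(keep))


def k_permutation_test(tree: PhyloTree, traits: Mapping[str, float] | pd.Series,
                       n_perm: int = 999, seed: int | None = None,
                       zero_length_epsilon: float = 1e-8) -> KResult:
    """Blomberg's K with a one-tailed permutation test for phylogenetic signal.

    The null distribution shuffles trait values across tips; large observed
    MSE0/MSE ratios (trait variance concentrated among distant relatives)
    indicate signal.  Ties count as exceedances (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    V, x, keep = _align_traits(tree, traits, zero_length_epsilon)
    Vinv, u, s, expected = _k_ingredients(V)
    observed = float(_mse_ratio(x[None, :], Vinv, u, s)[0])

    rng = np.random.default_rng(seed)
    X = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    null = _mse_ratio(X, Vinv, u, s)
    p = (1.0 + int(np.sum(null >= observed))) / (1.0 + n_perm)
    return KResult(k=observed / expected, observed_ratio=observed,
                   expected_ratio=expected, p=p, n_perm=n_perm, seed=seed,
                   n_tips_used=len(keep))


def trait_distance_matrix(trait_table: pd.DataFrame, labels: list[str] | None = None,
                          metric: str = "euclidean",
                          missing_policy: str = "pairwise") -> pd.DataFrame:
    """Pairwise Euclidean distances between row profiles of a trait table.

    missing_policy:
        "pairwise"  -- each pair uses only the columns where both rows are
                       non-missing (matching how sparse per-substrate traits
                       are compared across isolates);
        "complete"  -- rows are first restricted to columns with no missing
                       values anywhere.
    Rows with all-missing traits are dropped with a warning.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    table = trait_table.loc[labels] if labels is not None else trait_table
    if table.shape[0] < 2:
        raise ValueError("need at least two labels")
    all_missing = table.isna().all(axis=1)
    if all_missing.any():
        dropped = list(table.index[all_missing])
        warnings.warn(f"dropping labels with all-missing traits: {dropped}")
        table = table.loc[~all_missing]
    M = table.to_numpy(dtype=float)
    if missing_policy == "complete":
        M = M[:, ~np.isnan(M).any(axis=0)]
        if M.shape[1] == 0:
            raise ValueError("no complete columns available")
        diff = M[:, None, :] - M[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    elif missing_policy == "pairwise":
        mask = np.isfinite(M)
        Mz = np.where(mask, M, 0.0)
        diff = Mz[:, None, :] - Mz[None, :, :]
        both = mask[:, None, :] & mask[None, :, :]
        if not both.any(axis=2).all():
            raise ValueError("some label pairs share no observed trait columns")
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff * both, diff * both))
    else:
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=table.index, columns=table.index)


def _check_distance_matrix(D: pd.DataFrame, name: str) -> np.ndarray:
    A = np.asarray(D, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError(f"{name} is not symmetric")
    if np.abs(np.diag(A)).max() > 1e-12:
        raise ValueError(f"{name} has a nonzero diagonal")
    return A


def mantel(dist_a: pd.DataFrame, dist_b: pd.DataFrame, n_perm: int = 999,
           seed: int | None = None, exhaustive: bool = False) -> MantelResult:
    """One-tailed (positive) Mantel test between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the null
    permutes rows and columns of the second matrix simultaneously.  With
    ``exhaustive=True`` (feasible for small n) all n! permutations are
    enumerated and p is the exact fraction with r at least as large as
    observed (the identity permutation keeps p positive).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(dist_a.index) != set(dist_b.index):
        raise ValueError("distance matrices have different label sets")
    dist_b = dist_b.loc[dist_a.index, dist_a.index]
    A = _check_distance_matrix(dist_a, "dist_a")
    B = _check_distance_matrix(dist_b, "dist_b")
    n = A.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")

    tri = np.tril_indices(n, k=-1)
    a = A[tri]
    if np.ptp(a) == 0.0 or np.ptp(B[tri]) == 0.0:
        raise ValueError("zero variance in a distance-matrix lower triangle")

    def corr(bvec: np.ndarray) -> float:
        return float(np.corrcoef(a, bvec)[0, 1])

    observed = corr(B[tri])
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = sum(corr(B[np.ix_(perm, perm)][tri]) >= observed for perm in perms)
        return MantelResult(r=observed, p=count / len(perms), n_perm=len(perms),
                            seed=None, n_labels=n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr(B[np.ix_(perm, perm)][tri]) >= observed
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r=observed, p=p, n_perm=n_perm, seed=seed, n_labels=n)
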