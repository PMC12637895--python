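"""Phylogenetic covariance and phylogenetic-signal statistics.

Under Brownian-motion trait evolution on a rooted tree, tip values are
multivariate normal with covariance C[i,j] equal to the shared root-to-MRCA
branch length of tips i and j. Blomberg's K compares observed trait
dispersion against that Brownian expectation (K = 1 under pure BM); Pagel's
lambda rescales the off-diagonal of C and is estimated by maximum
likelihood with a boundary-corrected likelihood-ratio test against
lambda = 0 (no phylogenetic dependence).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve


@dataclasses.dataclass(frozen=True)
class PhyloSignalResult:
    statistic: str  # "K" or "lambda"
    estimate: float
    p_value: float
    null: str
    loglik: float | None = None
    loglik_null: float | None = None


def read_tree(path_or_string: str, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving underscores in tip labels."""
    kwargs = {"path": path_or_string} if is_path else {"data": path_or_string}
    tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    tree.is_rooted = True
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """Whether all root-to-tip distances agree within tol (not assumed anywhere)."""
    depths = _leaf_depths(tree)
    values = list(depths.values())
    return max(values) - min(values) <= tol * max(max(values), 1.0)


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        node._depth = (node.parent_node._depth if node.parent_node else 0.0) + edge
        if node.is_leaf():
            depths[node.taxon.label] = node._depth
    return depths


def phylo_vcv(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian variance-covariance matrix over an ordered taxon subset.

    The tree is pruned to the requested taxa first, which collapses
    unsampled lineages; C[i,j] is then the root-to-MRCA depth in the pruned
    tree and the diagonal holds root-to-tip distances.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for t in taxa:
        if t not in labels:
            raise ValueError(f"taxon {t!r} not found in tree")
    sub = tree.extract_tree_with_taxa_labels(labels=list(taxa))
    sub.is_rooted = True
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))

    # postorder accumulation: a node's depth is the covariance of every
    # cross-child leaf pair whose MRCA it is
    for node in sub.preorder_node_iter():
        edge = node.edge.length or 0.0
        node._depth = (node.parent_node._depth if node.parent_node else 0.0) + edge
    for node in sub.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node._leaves = [i]
            C[i, i] = node._depth
        else:
            groups = [child._leaves for child in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = node._depth
            node._leaves = [i for g in groups for i in g]
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda rescaling: off-diagonals multiplied by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda outside [0, 1]")
    out = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(out, np.diag(C))
    return out


def _chol(C: np.ndarray):
    """Cholesky with a tiny escalating ridge; trees with near-zero terminal
    branches give numerically singular (but valid PSD) covariances."""
    for ridge in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return cho_factor(C + ridge * np.mean(np.diag(C)) * np.eye(len(C)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is not positive semidefinite")


def _trait_vector(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> tuple[np.ndarray, list[str]]:
    taxa = list(trait.keys())
    x = np.array([float(trait[t]) for t in taxa])
    if len(taxa) < 3:
        raise ValueError("need at least 3 tips")
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")
    return x, taxa


def blomberg_k(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> PhyloSignalResult:
    """Blomberg's K with a tip-label permutation test.

    K is the ratio of observed to Brownian-expected (MSE0/MSE), where MSE0
    is the mean squared deviation from the phylogenetic GLS mean and MSE
    the C-weighted one; the permutation null shuffles trait values across
    tips (the standard randomization for K's p-value; the BM expectation
    enters through the denominator).
    """
    x, taxa = _trait_vector(tree, trait)
    C = phylo_vcv(tree, taxa)
    n = len(x)
    chol = _chol(C)
    Cinv_one = cho_solve(chol, np.ones(n))
    s = float(np.ones(n) @ Cinv_one)
    expected = (np.trace(C) - n / s) / (n - 1)

    def k_stat(cols: np.ndarray) -> np.ndarray:
        # cols: (n, m) trait columns; returns K per column
        a_hat = (Cinv_one @ cols) / s
        num = ((cols - a_hat) ** 2).sum(axis=0)
        Y = cho_solve(chol, cols)
        quad = (cols * Y).sum(axis=0)
        one_y = Cinv_one @ cols
        den = quad - 2 * a_hat * one_y + a_hat**2 * s
        return (num / den) / expected

    k_obs = float(k_stat(x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(x)
    k_perm = k_stat(perms)
    p = (1 + int(np.sum(k_perm >= k_obs))) / (n_perm + 1)
    return PhyloSignalResult(
        statistic="K",
        estimate=k_obs,
        p_value=float(p),
        null=f"tip-label permutation, n_perm={n_perm}, seed={seed}",
    )


def _lambda_profile_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    n = len(x)
    Clam = lambda_transform(C, lam)
    try:
        chol = _chol(Clam)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    Cinv_one = cho_solve(chol, np.ones(n))
    s = float(np.ones(n) @ Cinv_one)
    mu = float(Cinv_one @ x) / s
    r = x - mu
    sigma2 = float(r @ cho_solve(chol, r)) / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda_ml(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda with a boundary-corrected LRT.

    The mean and Brownian rate are profiled analytically; lambda is found
    by bounded 1-D optimization on [0, 1] with restarts, and the LRT
    against lambda = 0 uses the 50:50 chi-square mixture appropriate for a
    parameter on its boundary (p = 1 when the estimate is exactly 0).
    """
    x, taxa = _trait_vector(tree, trait)
    C = phylo_vcv(tree, taxa)

    def neg(lam: float) -> float:
        return -_lambda_profile_loglik(x, C, lam)

    candidates = [(lam, neg(lam)) for lam in (0.0, 0.5, 1.0)]
    for lo, hi in ((0.0, 0.5), (0.5, 1.0), (0.0, 1.0)):
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        candidates.append((float(res.x), float(res.fun)))
    lam_hat, neg_best = min(candidates, key=lambda c: c[1])
    ll_hat = -neg_best
    ll_null = _lambda_profile_loglik(x, C, 0.0)
    if not np.isfinite(ll_hat):
        raise ValueError("non-finite likelihood in lambda optimization")
    lrt = max(2.0 * (ll_hat - ll_null), 0.0)
    p = 1.0 if lrt <= 1e-10 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return PhyloSignalResult(
        statistic="lambda",
        estimate=float(np.clip(lam_hat, 0.0, 1.0)),
        p_value=p,
        null="LRT vs lambda=0, 0.5*chi2(1) boundary mixture",
        loglik=ll_hat,
        loglik_null=ll_null,
    )
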