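"""Independent oracles: brute-force implementations used only by tests."""

from __future__ import annotations

import numpy as np
import dendropy
from scipy.linalg import expm

from heteropecilly.alignment import AMINO_ACIDS

N = 20


def poisson_rate_matrix(pi: np.ndarray) -> np.ndarray:
    """Generator of the equal-exchangeability process, unit expected rate."""
    beta = 1.0 / (1.0 - float(pi @ pi))
    Q = beta * np.tile(pi, (N, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def brute_force_site_loglik(tree: dendropy.Tree, column: dict[str, str],
                            pi: np.ndarray, rate: float = 1.0) -> float:
    """Explicit sum over all internal-node state assignments.

    Transition probabilities come from the matrix exponential of the rate
    matrix (not the closed form), and the likelihood is a literal sum over
    the full grid of internal states, so this path shares nothing with the
    pruning implementation.
    """
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    ax = {id(nd): i for i, nd in enumerate(internal)}
    m = len(internal)
    grid = np.ones((N,) * m)
    root = tree.seed_node
    shape_root = [1] * m
    shape_root[ax[id(root)]] = N
    grid = grid * pi.reshape(shape_root)
    for nd in nodes:
        if nd is root:
            continue
        P = expm(poisson_rate_matrix(pi) * rate * nd.edge.length)
        p_ax = ax[id(nd.parent_node)]
        if nd.is_leaf():
            sym = column[nd.taxon.label]
            if sym not in AMINO_ACIDS:
                continue  # missing leaf: sums to 1
            vec = P[:, AMINO_ACIDS.index(sym)]
            shape = [1] * m
            shape[p_ax] = N
            grid = grid * vec.reshape(shape)
        else:
            c_ax = ax[id(nd)]
            shape = [1] * m
            shape[p_ax] = N
            shape[c_ax] = N
            if p_ax < c_ax:
                mat = P
            else:
                mat = P.T
            grid = grid * mat.reshape(
                [N if k in (p_ax, c_ax) else 1 for k in range(m)])
    return float(np.log(grid.sum()))


def random_tree(n_leaves: int, rng: np.random.Generator,
                max_branch: float = 1.5) -> tuple[dendropy.Tree, list[str]]:
    """Random binary topology with uniform branch lengths, as Newick."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    nodes = list(taxa)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.01, max_branch, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    tree = dendropy.Tree.get(data=nodes[0] + ";", schema="newick",
                             preserve_underscores=True)
    return tree, taxa


def random_profile(rng: np.random.Generator, concentration: float = 0.5
                   ) -> np.ndarray:
    return rng.dirichlet(np.full(N, concentration))


def brute_force_upgma(D: np.ndarray, cut: float) -> list[set[int]]:
    """Naive average-linkage agglomeration cut at a height.

    Cluster distance is the mean of the original pairwise distances across
    the two clusters; merges happen closest-pair-first while the closest
    distance is at most ``cut``.
    """
    clusters = [{i} for i in range(D.shape[0])]
    while len(clusters) > 1:
        best, bi, bj = np.inf, -1, -1
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best - 1e-15:
                    best, bi, bj = d, i, j
        if best > cut:
            break
        clusters[bi] = clusters[bi] | clusters[bj]
        del clusters[bj]
    return clusters
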