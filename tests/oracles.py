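"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: exhaustive enumeration, direct dynamic programming,
or explicit design-matrix least squares.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

from siterates.trees import IndexedTree


def equal_exchange_p_entry(t: float, same: bool) -> float:
    e = math.exp(-20.0 / 19.0 * t)
    return 1.0 / 20 + 19.0 / 20 * e if same else 1.0 / 20 - e / 20


def enumeration_site_likelihood(
    tree: IndexedTree, leaf_codes: list[int], rate: float
) -> float:
    """Column likelihood by summing over all internal-node (and missing-leaf)
    state assignments; feasible for trees with <= 4 leaves."""
    parent: dict[int, int] = {}
    for n in tree.postorder:
        for c in tree.children[n]:
            parent[c] = n
    internal = [n for n in tree.postorder if tree.children[n]]
    missing = [n for n in range(tree.n_leaves) if leaf_codes[n] < 0]
    var_nodes = internal + missing
    terms = []
    for assign in itertools.product(range(20), repeat=len(var_nodes)):
        state = dict(zip(var_nodes, assign))
        for leaf in range(tree.n_leaves):
            if leaf_codes[leaf] >= 0:
                state[leaf] = leaf_codes[leaf]
        factors = [1.0 / 20]  # uniform root frequency
        for n in range(tree.n_nodes):
            if n == tree.root:
                continue
            factors.append(
                equal_exchange_p_entry(
                    tree.branch_lengths[n] * rate, state[n] == state[parent[n]]
                )
            )
        terms.append(math.prod(factors))
    return math.fsum(terms)


def smith_waterman_affine(
    s1: str, s2: str, open_cost: float = 12.0, extend_cost: float = 1.0
) -> float:
    """Best local alignment score, Gotoh three-matrix DP, BLOSUM62.

    ``open_cost`` is the cost of the first gapped column (BLAST 11/1 ->
    12 for the first column, 1 for each further column).
    """
    B = substitution_matrices.load("BLOSUM62")
    n, m = len(s1), len(s2)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost)
            s = B[s1[i - 1], s2[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            M[i, j] = max(M[i, j], 0.0)
            best = max(best, M[i, j], Ix[i, j], Iy[i, j])
    return float(best)


def type3_ss_oracle(df) -> dict[str, float]:
    """Type-III sums of squares by explicit full-vs-reduced effects-coded
    design matrices (residual-SS differences)."""
    x1 = np.where(df.disorder == "disordered", 1.0, -1.0)
    x2 = np.where(df.ss == "coil", 1.0, -1.0)
    x3 = np.where(df.domain == "linker", 1.0, -1.0)
    cols = {
        "disorder": x1,
        "ss": x2,
        "domain": x3,
        "disorder:ss": x1 * x2,
        "disorder:domain": x1 * x3,
        "ss:domain": x2 * x3,
        "disorder:ss:domain": x1 * x2 * x3,
    }
    y = df.z_rate.to_numpy()
    ones = np.ones(len(y))

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    names = list(cols)
    full = np.column_stack([ones] + [cols[n] for n in names])
    rss_full = rss(full)
    out = {}
    for n in names:
        reduced = np.column_stack([ones] + [cols[m] for m in names if m != n])
        out[n] = rss(reduced) - rss_full
    return out


def brute_force_components(ids: list[str], edges: list[tuple[str, str]]):
    """Connected components by plain DFS (no union-find)."""
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps
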