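"""Differential network, CRV statistic, and the permutation null.

The differential network for one cancer is D = A_cancer - A_normal; the
carcinogenesis relevance value of protein i is the absolute row sum

    CRV_i = sum_{j != i} |d_ij|,

the total change in interaction ability of protein i between conditions.
Significance is assessed against a degree-preserving permutation null: the
support graph of D is rewired by repeated double-edge swaps (each protein
keeps its number of interactions) and the observed edge weights are carried
onto the rewired edges in shuffled order; CRVs are recomputed per draw and

    p_i = (1 + #{draws with CRV_i >= observed}) / (1 + n_permutations),

the add-one empirical p-value, which can never be exactly zero.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import CRVTable, DifferentialNetwork, InteractionMatrix

logger = logging.getLogger(__name__)

#: attempted double-edge swaps per permutation draw, as a multiple of |edges|
SWAPS_PER_EDGE = 4


def differential_matrix(
    A_cancer: InteractionMatrix,
    A_normal: InteractionMatrix,
) -> DifferentialNetwork:
    """Elementwise D = A_cancer - A_normal over a shared protein ordering."""
    if A_cancer.protein_ids != A_normal.protein_ids:
        sym_diff = set(A_cancer.protein_ids) ^ set(A_normal.protein_ids)
        if sym_diff:
            raise ValueError(f"protein sets differ: {sorted(sym_diff)}")
        raise ValueError("protein ids must be in the same order in both matrices")
    if A_cancer.cancer_id != A_normal.cancer_id:
        raise ValueError(
            f"cancer ids differ: {A_cancer.cancer_id!r} vs {A_normal.cancer_id!r}"
        )
    return DifferentialNetwork(
        protein_ids=A_cancer.protein_ids,
        D=A_cancer.A - A_normal.A,
        cancer_id=A_cancer.cancer_id,
    )


def crv(diff: DifferentialNetwork) -> np.ndarray:
    """CRV_i = absolute row sum of D (diagonal is zero by construction)."""
    return np.abs(diff.D).sum(axis=1)


def _crv_from_edges(n: int, u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.zeros(n)
    np.add.at(out, u, np.abs(w))
    np.add.at(out, v, np.abs(w))
    return out


def _double_edge_swap(
    u: np.ndarray, v: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rewire an undirected simple edge list by double-edge swaps.

    A swap picks two edges (a,b),(c,d) and proposes (a,d),(c,b); it is
    rejected if it would create a self-loop or a multi-edge, so the degree
    sequence and simplicity are invariants of every accepted swap.
    """
    m = len(u)
    u = u.copy()
    v = v.copy()
    present = {(min(a, b), max(a, b)) for a, b in zip(u.tolist(), v.tolist())}
    picks = rng.integers(0, m, size=(n_attempts, 2))
    coin = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if coin[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 == new2 or new1 in present or new2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        u[e1], v[e1] = new1
        u[e2], v[e2] = new2
    return u, v


def rewire_preserving_degree(
    edges: set[tuple[str, str]] | frozenset[tuple[str, str]],
    n_swaps: int,
    seed: int,
) -> frozenset[tuple[str, str]]:
    """Degree-preserving rewiring of an undirected edge set.

    Performs ``n_swaps`` attempted double-edge swaps; graphs with fewer
    than two edges are returned unchanged with a warning.
    """
    edge_list = sorted((a, b) if a < b else (b, a) for a, b in edges)
    if any(a == b for a, b in edge_list):
        raise ValueError("self-loops are not allowed")
    if len(edge_list) < 2:
        logger.warning("fewer than 2 edges: no legal double-edge swap, returning input")
        return frozenset(edge_list)
    nodes = sorted({x for e in edge_list for x in e})
    index = {x: i for i, x in enumerate(nodes)}
    u = np.array([index[a] for a, _ in edge_list])
    v = np.array([index[b] for _, b in edge_list])
    rng = np.random.default_rng(seed)
    u, v = _double_edge_swap(u, v, n_swaps, rng)
    return frozenset(
        (nodes[min(a, b)], nodes[max(a, b)]) for a, b in zip(u.tolist(), v.tolist())
    )


def permutation_pvalues(
    diff: DifferentialNetwork,
    n_permutations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> CRVTable:
    """Empirical per-protein CRV p-values under the degree-preserving null.

    Each draw rewires the support graph of D (proteins keep their number
    of changed interactions) and carries the observed weights onto the
    rewired edges in shuffled order before recomputing all CRVs.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = len(diff.protein_ids)
    iu, ju = np.nonzero(np.triu(diff.D, k=1))
    weights = diff.D[iu, ju]
    observed = crv(diff)
    if len(iu) == 0:
        logger.warning("differential network is empty: all p-values are 1")
        return CRVTable(protein_ids=diff.protein_ids, crv=observed,
                        pvalue=np.ones(n), n_permutations=n_permutations,
                        alpha=alpha, seed=seed, cancer_id=diff.cancer_id)
    rng = np.random.default_rng(seed)
    n_attempts = SWAPS_PER_EDGE * len(iu)
    exceed = np.zeros(n, dtype=np.int64)
    tol = 1e-12  # >= comparisons robust to float round-off in the row sums
    for _ in range(n_permutations):
        pu, pv = _double_edge_swap(iu, ju, n_attempts, rng)
        pw = weights[rng.permutation(len(weights))]
        perm_crv = _crv_from_edges(n, pu, pv, pw)
        exceed += perm_crv >= observed - tol
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    return CRVTable(protein_ids=diff.protein_ids, crv=observed, pvalue=pvals,
                    n_permutations=n_permutations, alpha=alpha, seed=seed,
                    cancer_id=diff.cancer_id)


def significant_proteins(table: CRVTable) -> list[str]:
    """Proteins with p <= alpha, sorted by descending CRV (ties by id)."""
    rows = [
        (float(-table.crv[i]), pid)
        for i, pid in enumerate(table.protein_ids)
        if table.pvalue[i] <= table.alpha
    ]
    return [pid for _, pid in sorted(rows)]
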