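"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the three study inputs: (a) expression matrices from
a linear Gaussian association model, (b) candidate interaction networks
(true edges plus planted false positives), and (c) docking-score tables
with planted multi-target ligands.

The association model is a simultaneous system x = A x + w: a sample is the
unique solution x = (I - A)^{-1} w, which exists whenever the spectral
radius of A is below one. Edge weights are drawn uniform on +/-[0.2, 0.8];
if any condition matrix has spectral radius >= 0.95, *all* matrices are
scaled by a common factor so perturbation locality is preserved (the factor
is recorded on the scenario).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .types import (
    DockingScoreTable,
    Edge,
    ExpressionMatrix,
    GroundTruthScenario,
    canonical_edge,
)

logger = logging.getLogger(__name__)

#: spectral-radius ceiling after rescaling; keeps (I - A) well conditioned
STABILITY_RADIUS = 0.95

#: minimum network degree for a protein to be eligible as a planted marker.
#: A perturbation is only identifiable by a degree-preserving permutation
#: null when it touches several interactions; published network markers are
#: correspondingly hub-like.
MIN_PERTURBED_DEGREE = 4


def _spectral_radius(A: np.ndarray) -> float:
    return float(max(abs(np.linalg.eigvals(A))))


def generate_ground_truth(
    M: int,
    edge_density: float,
    n_cancers: int,
    core_size: int,
    specific_size: int = 0,
    effect_size: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> GroundTruthScenario:
    """Plant a shared normal network and per-cancer perturbed variants.

    Each cancer matrix equals the normal matrix except on rows/columns of
    its perturbed proteins (the shared core plus its own specific set),
    whose incident edge weights are shifted by +/-``effect_size``.
    Perturbed proteins are drawn among hub-like nodes (degree >=
    ``MIN_PERTURBED_DEGREE``), since an interaction perturbation on a
    near-isolated node is unidentifiable under a degree-preserving null.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    if not (0 < edge_density < 1):
        raise ValueError(f"edge_density must lie in (0, 1), got {edge_density}")
    if n_cancers < 1:
        raise ValueError("n_cancers must be at least 1")
    if core_size < 0 or specific_size < 0:
        raise ValueError("set sizes must be non-negative")
    if core_size + n_cancers * specific_size > M:
        raise ValueError(
            f"core_size + n_cancers*specific_size = "
            f"{core_size + n_cancers * specific_size} exceeds M = {M}"
        )
    n_pairs = M * (M - 1) // 2
    if edge_density * n_pairs < 1:
        raise ValueError("edge_density too low: expected edge count below 1")

    rng = np.random.default_rng(seed)
    protein_ids = tuple(f"P{i:03d}" for i in range(M))

    # Erdos-Renyi support with uniform +/-[0.2, 0.8] weights, stabilized
    # *before* perturbation so the planted shift keeps its stated magnitude
    pairs = list(combinations(range(M), 2))
    present = rng.random(n_pairs) < edge_density
    A_normal = np.zeros((M, M))
    for (i, j), keep in zip(pairs, present):
        if keep:
            w = rng.uniform(0.2, 0.8) * rng.choice([-1.0, 1.0])
            A_normal[i, j] = A_normal[j, i] = w
    rho_base = _spectral_radius(A_normal)
    if rho_base >= STABILITY_RADIUS:
        logger.info("stabilizing base network: scaling by %.4f (spectral radius %.3f)",
                    STABILITY_RADIUS / rho_base, rho_base)
        A_normal = A_normal * (STABILITY_RADIUS / rho_base)

    degree = (A_normal != 0).sum(axis=0)
    eligible = [i for i in range(M) if degree[i] >= MIN_PERTURBED_DEGREE]
    n_needed = core_size + n_cancers * specific_size
    if len(eligible) < n_needed:
        # fall back to the highest-degree nodes available
        eligible = sorted(range(M), key=lambda i: (-degree[i], i))[:max(n_needed, 1)]
    chosen = rng.choice(np.array(sorted(eligible)), size=n_needed, replace=False) \
        if n_needed else np.array([], dtype=int)
    core_idx = sorted(int(i) for i in chosen[:core_size])
    cancer_ids = tuple(f"cancer{k + 1}" for k in range(n_cancers))
    specific_idx: dict[str, list[int]] = {}
    off = core_size
    for cid in cancer_ids:
        specific_idx[cid] = sorted(int(i) for i in chosen[off:off + specific_size])
        off += specific_size

    A_cancer: dict[str, np.ndarray] = {}
    for cid in cancer_ids:
        Ak = A_normal.copy()
        for i in core_idx + specific_idx[cid]:
            for j in np.nonzero(A_normal[i])[0]:
                if Ak[i, j] != A_normal[i, j]:
                    continue  # already shifted via the other endpoint
                # carcinogenic rewiring modeled as weakening/reversal of the
                # normal interaction: the differential entry keeps magnitude
                # effect_size and the perturbation stays spectrally
                # incoherent with the baseline (coherent strengthening would
                # force a large stability rescale of the whole system)
                shift = -effect_size * np.sign(A_normal[i, j])
                Ak[i, j] += shift
                Ak[j, i] = Ak[i, j]
        A_cancer[cid] = Ak

    rho = max([_spectral_radius(A_normal)] + [_spectral_radius(A) for A in A_cancer.values()])
    factor = 1.0
    if rho >= STABILITY_RADIUS:
        factor = STABILITY_RADIUS / rho
        logger.info("rescaling all condition matrices by %.4f (max spectral radius %.3f)",
                    factor, rho)
        A_normal = A_normal * factor
        A_cancer = {cid: A * factor for cid, A in A_cancer.items()}

    return GroundTruthScenario(
        protein_ids=protein_ids,
        A_normal=A_normal,
        A_cancer_per_type=A_cancer,
        perturbed_core=frozenset(protein_ids[i] for i in core_idx),
        perturbed_specific={cid: frozenset(protein_ids[i] for i in idx)
                            for cid, idx in specific_idx.items()},
        noise_sd=noise_sd,
        seed=seed,
        rescale_factor=factor,
    )


def simulate_expression(
    A: np.ndarray,
    n_samples: int,
    noise_sd: float,
    seed: int,
    protein_ids: tuple[str, ...] | None = None,
    condition: str = "normal",
    cancer_id: str = "",
) -> ExpressionMatrix:
    """Sample expression columns solving x = A x + w, i.e. x = (I-A)^{-1} w."""
    A = np.asarray(A, dtype=float)
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    M = A.shape[0]
    rho = _spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(f"spectral radius {rho:.3f} >= 1: system has no stable solution")
    rng = np.random.default_rng(seed)
    omega = rng.normal(0.0, noise_sd, size=(M, n_samples))
    values = np.linalg.solve(np.eye(M) - A, omega)
    if protein_ids is None:
        protein_ids = tuple(f"P{i:03d}" for i in range(M))
    sample_ids = tuple(f"S{j:04d}" for j in range(n_samples))
    return ExpressionMatrix(protein_ids=protein_ids, sample_ids=sample_ids,
                            values=values, condition=condition, cancer_id=cancer_id)


def make_candidate_network(
    truth: GroundTruthScenario,
    fp_edges: int,
    seed: int,
) -> tuple[frozenset[Edge], dict[Edge, bool]]:
    """True edge set plus planted false-positive pairs.

    Returns ``(candidate_edges, labels)`` where ``labels[edge]`` is True for
    a true interaction and False for a planted false positive.
    """
    if fp_edges < 0:
        raise ValueError("fp_edges must be non-negative")
    true = truth.true_edges()
    ids = truth.protein_ids
    all_pairs = [canonical_edge(a, b) for a, b in combinations(ids, 2)]
    non_edges = sorted(e for e in all_pairs if e not in true)
    if fp_edges > len(non_edges):
        raise ValueError(f"fp_edges={fp_edges} exceeds {len(non_edges)} available non-edges")
    rng = np.random.default_rng(seed)
    fp_idx = rng.choice(len(non_edges), size=fp_edges, replace=False) if fp_edges else []
    fps = frozenset(non_edges[i] for i in fp_idx)
    labels = {e: True for e in true} | {e: False for e in fps}
    return frozenset(true | fps), labels


def generate_docking_scores(
    protein_ids: list[str],
    n_drugs: int,
    n_multi_target: int,
    targets_per_multi: int = 2,
    score_range: tuple[float, float] = (50.0, 150.0),
    top_k: int = 20,
    seed: int = 0,
) -> tuple[DockingScoreTable, frozenset[str]]:
    """Score table with exactly ``n_multi_target`` planted multi-target drugs.

    Background drugs are each docked against a single protein with scores
    uniform on ``score_range``. Each planted drug is docked against
    ``targets_per_multi`` distinct proteins with scores in the top tenth of
    the range, guaranteeing a place in any top-k shortlist of size >= 1
    drawn from at most ``top_k`` background compounds per protein.
    Returns the table and the planted drug ids.
    """
    if not protein_ids:
        raise ValueError("protein_ids must be non-empty")
    lo, hi = score_range
    if not (hi > lo):
        raise ValueError(f"degenerate score_range {score_range}")
    if n_multi_target > n_drugs:
        raise ValueError("n_multi_target cannot exceed n_drugs")
    if n_multi_target and targets_per_multi < 2:
        raise ValueError("targets_per_multi must be at least 2")
    if targets_per_multi > len(protein_ids):
        raise ValueError("targets_per_multi exceeds number of proteins")

    rng = np.random.default_rng(seed)
    proteins = list(protein_ids)
    records: list[tuple[str, str, float]] = []
    planted = [f"D{d:04d}" for d in range(n_multi_target)]
    cut = lo + 0.9 * (hi - lo)  # planted scores sit above every background score
    for drug in planted:
        targets = rng.choice(len(proteins), size=targets_per_multi, replace=False)
        for t in targets:
            records.append((drug, proteins[t], float(rng.uniform(cut, hi))))
    # single-target background: ensure every protein has at least top_k entries
    n_background = n_drugs - n_multi_target
    d = n_multi_target
    per_protein = {p: 0 for p in proteins}
    while n_background > 0 or min(per_protein.values()) < top_k:
        p = proteins[int(rng.integers(len(proteins)))] if n_background > 0 else \
            min(per_protein, key=lambda q: (per_protein[q], q))
        records.append((f"D{d:04d}", p, float(rng.uniform(lo, cut))))
        per_protein[p] += 1
        d += 1
        n_background -= 1
    frame = pd.DataFrame(records, columns=["drug_id", "protein_id", "score"])
    return DockingScoreTable(frame=frame), frozenset(planted)
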