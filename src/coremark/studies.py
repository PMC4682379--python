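"""Simulation studies quantifying the pipeline's operating characteristics.

Each study runs the full inference stack on generator output under fixed
study conditions and reports a summary metric: oracle agreement for the
search heuristics, edge-pruning sensitivity/specificity, coefficient
recovery error, permutation-null calibration, and detection power for
planted markers. The scenario sizes are part of the study design and are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .cocktail import (
    brute_force_min_cover,
    greedy_min_cover,
    multi_target_ligands,
    top_k_ligands,
)
from .diffnet import differential_matrix, permutation_pvalues, significant_proteins
from .inference import aic_order_select, infer_ppin
from .synthetic import (
    generate_docking_scores,
    generate_ground_truth,
    make_candidate_network,
    simulate_expression,
)
from .types import ExpressionMatrix


def _retained_edges(mat):
    ids = mat.protein_ids
    iu, ju = np.nonzero(np.triu(mat.A, 1))
    return {(ids[i], ids[j]) for i, j in zip(iu, ju)}


def aic_oracle_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Forward-stepwise vs exhaustive AIC subset choice on random regressions.

    Instances have <= 8 i.i.d. Gaussian candidate regressors, 0-3 true
    effects of magnitude 0.3-0.8, n=100 samples.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = 100
        k = int(rng.integers(3, 9))
        X = rng.normal(size=(n, k))
        n_true = int(rng.integers(0, min(3, k) + 1))
        beta = np.zeros(k)
        idx = rng.choice(k, n_true, replace=False)
        beta[idx] = rng.uniform(0.3, 0.8, n_true) * rng.choice([-1.0, 1.0], n_true)
        y = X @ beta + rng.normal(0, 1.0, n)
        ids = tuple(f"P{i:02d}" for i in range(k + 1))
        expr = ExpressionMatrix(protein_ids=ids,
                                sample_ids=tuple(f"S{j}" for j in range(n)),
                                values=np.vstack([y, X.T]))
        fwd, _ = aic_order_select(expr, ids[0], list(ids[1:]))
        exh, _ = aic_order_select(expr, ids[0], list(ids[1:]), exhaustive=True)
        agree += set(fwd) == set(exh)
    return {"agreement": agree / n_instances, "n": n_instances}


def cover_oracle_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Greedy cover size vs exhaustive optimum on random covering instances.

    4-12 drugs over universes of 4-10 proteins with Bernoulli(0.35)
    coverage; empty coverage sets are redrawn.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n_drugs = int(rng.integers(4, 13))
        n_prot = int(rng.integers(4, 11))
        universe = {f"P{i}" for i in range(n_prot)}
        cands = {}
        for d in range(n_drugs):
            cov = {p for p in universe if rng.random() < 0.35}
            while not cov:
                cov = {p for p in universe if rng.random() < 0.35}
            cands[f"D{d:02d}"] = frozenset(cov)
        plan = greedy_min_cover(cands, universe)
        agree += len(plan.selected_drugs) == brute_force_min_cover(cands, universe)
    return {"agreement": agree / n_instances, "n": n_instances}


def parameter_recovery_study(n_reps: int = 5, seed: int = 600) -> dict:
    """Mean absolute error of retained coefficients vs planted weights.

    M=20 proteins at edge density 0.2, n=1000 samples, noise 0.1, clean
    candidate network (no planted false positives).
    """
    errs: list[float] = []
    for r in range(n_reps):
        truth = generate_ground_truth(M=20, edge_density=0.2, n_cancers=1,
                                      core_size=0, specific_size=0,
                                      effect_size=0.0, noise_sd=0.1, seed=seed + r)
        cand, _ = make_candidate_network(truth, 0, seed=seed + 100 + r)
        expr = simulate_expression(truth.A_normal, 1000, 0.1, seed=seed + 200 + r,
                                   protein_ids=truth.protein_ids)
        mat = infer_ppin(expr, cand)
        idx = {p: i for i, p in enumerate(truth.protein_ids)}
        for a, b in cand:
            i, j = idx[a], idx[b]
            if mat.A[i, j] != 0:
                errs.append(abs(mat.A[i, j] - truth.A_normal[i, j]))
    return {"mae": float(np.mean(errs)), "n": len(errs)}


def pruning_study(n_reps: int = 10, seed: int = 300) -> dict:
    """Candidate-edge pruning quality against planted true/false labels.

    M=30 proteins at density 0.1 with 20 planted false-positive edges,
    n=200 samples, noise 0.3 (normal condition of an effect-0.5 scenario).
    """
    sens, spec = [], []
    for r in range(n_reps):
        truth = generate_ground_truth(M=30, edge_density=0.1, n_cancers=1,
                                      core_size=2, specific_size=0,
                                      effect_size=0.5, noise_sd=0.3, seed=seed + r)
        cand, labels = make_candidate_network(truth, 20, seed=seed + 100 + r)
        expr = simulate_expression(truth.A_normal, 200, 0.3, seed=seed + 200 + r,
                                   protein_ids=truth.protein_ids)
        retained = _retained_edges(infer_ppin(expr, cand))
        true_e = {e for e, t in labels.items() if t}
        false_e = {e for e, t in labels.items() if not t}
        sens.append(len(retained & true_e) / len(true_e))
        spec.append(len(false_e - retained) / len(false_e))
    return {"sensitivity": float(np.mean(sens)), "specificity": float(np.mean(spec)),
            "n": n_reps}


def null_calibration_study(n_reps: int = 50, n_permutations: int = 1000,
                           seed: int = 1) -> dict:
    """Fraction of proteins flagged at p<=0.01 when conditions are identical.

    Two independent expression sets from the same 20-protein network
    (density 0.15, n=100/condition) are run through the full inference +
    CRV + permutation stack; any flags are false positives.
    """
    flagged, total = 0, 0
    for r in range(n_reps):
        truth = generate_ground_truth(M=20, edge_density=0.15, n_cancers=1,
                                      core_size=0, specific_size=0,
                                      effect_size=0.0, noise_sd=0.3, seed=seed + r)
        cand, _ = make_candidate_network(truth, 10, seed=seed + 1000 + r)
        cid = next(iter(truth.A_cancer_per_type))
        e1 = simulate_expression(truth.A_normal, 100, 0.3, seed=seed + 2000 + r,
                                 protein_ids=truth.protein_ids, cancer_id=cid)
        e2 = simulate_expression(truth.A_normal, 100, 0.3, seed=seed + 3000 + r,
                                 protein_ids=truth.protein_ids,
                                 condition="cancer", cancer_id=cid)
        diff = differential_matrix(infer_ppin(e2, cand), infer_ppin(e1, cand))
        table = permutation_pvalues(diff, n_permutations=n_permutations,
                                    alpha=0.01, seed=seed + 4000 + r)
        flagged += int(table.significant.sum())
        total += len(table.protein_ids)
    return {"fraction_flagged": flagged / total, "n": n_reps}


def power_study(n_reps: int = 20, n_permutations: int = 1000, seed: int = 100) -> dict:
    """Sensitivity/FPR for planted perturbed proteins at alpha 0.01.

    M=40 proteins at density 0.15, a 3-protein perturbed core, effect 0.5,
    noise 0.3, n=200 samples per condition.
    """
    sens, fpr = [], []
    M = 40
    for r in range(n_reps):
        s = seed + r
        truth = generate_ground_truth(M=M, edge_density=0.15, n_cancers=1,
                                      core_size=3, specific_size=0,
                                      effect_size=0.5, noise_sd=0.3, seed=s)
        cand, _ = make_candidate_network(truth, 20, seed=s + 11)
        cid = next(iter(truth.A_cancer_per_type))
        en = simulate_expression(truth.A_normal, 200, 0.3, seed=s + 17,
                                 protein_ids=truth.protein_ids, cancer_id=cid)
        ec = simulate_expression(truth.A_cancer_per_type[cid], 200, 0.3, seed=s + 23,
                                 protein_ids=truth.protein_ids,
                                 condition="cancer", cancer_id=cid)
        diff = differential_matrix(infer_ppin(ec, cand), infer_ppin(en, cand))
        table = permutation_pvalues(diff, n_permutations=n_permutations,
                                    alpha=0.01, seed=s + 29)
        sig = set(significant_proteins(table))
        core = truth.perturbed_core
        sens.append(len(sig & core) / len(core))
        fpr.append(len(sig - core) / (M - len(core)))
    return {"sensitivity": float(np.mean(sens)), "fpr": float(np.mean(fpr)),
            "n": n_reps}


def cocktail_recovery_study(seed: int = 0) -> dict:
    """Planted multi-target ligand recovery and greedy coverage on one table."""
    proteins = [f"P{i:02d}" for i in range(8)]
    table, planted = generate_docking_scores(proteins, n_drugs=60, n_multi_target=3,
                                             targets_per_multi=3, top_k=10, seed=seed)
    multi = multi_target_ligands(top_k_ligands(table, 10), 2)
    plan = greedy_min_cover(multi, set().union(*multi.values()) if multi else set(),
                            scores=table)
    return {
        "planted_recovered": float(set(multi) == planted),
        "n_selected": len(plan.selected_drugs),
        "n_covered": len(plan.covered_proteins),
    }
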