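"""Multi-target ligand selection over docking-score tables.

Per-protein top-k shortlists are taken from the score table, redundancy
analysis identifies ligands shortlisted by two or more proteins, and a
greedy set cover picks a minimal drug package jointly covering the target
proteins. Docking scores are never compared across proteins except to
break ties: scores from different binding sites are not calibrated
against each other.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping

from .types import CocktailPlan, CRVSumTable, DockingScoreTable

logger = logging.getLogger(__name__)


def top_k_ligands(table: DockingScoreTable, k: int) -> dict[str, list[str]]:
    """Per protein, the k highest-scoring drugs in descending score order.

    Score ties break by drug id; a protein with fewer than k docked drugs
    returns them all with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    df = table.frame
    if df.empty:
        raise ValueError("empty docking-score table")
    shortlists: dict[str, list[str]] = {}
    for protein, group in df.groupby("protein_id", sort=True):
        ordered = group.sort_values(["score", "drug_id"], ascending=[False, True],
                                    kind="mergesort")
        if len(ordered) < k:
            logger.warning("protein %s has only %d docked drugs (k=%d)",
                           protein, len(ordered), k)
        shortlists[str(protein)] = [str(d) for d in ordered["drug_id"].head(k)]
    return shortlists


def multi_target_ligands(
    shortlists: Mapping[str, list[str]],
    min_targets: int = 2,
) -> dict[str, frozenset[str]]:
    """Drugs shortlisted by at least ``min_targets`` distinct proteins.

    Returned in deterministic order: descending number of targets, then
    drug id.
    """
    if not shortlists:
        raise ValueError("shortlists must be non-empty")
    if min_targets < 1:
        raise ValueError("min_targets must be at least 1")
    hits: dict[str, set[str]] = {}
    for protein, drugs in shortlists.items():
        for d in drugs:
            hits.setdefault(d, set()).add(protein)
    multi = {d: frozenset(ps) for d, ps in hits.items() if len(ps) >= min_targets}
    ordered = sorted(multi, key=lambda d: (-len(multi[d]), d))
    return {d: multi[d] for d in ordered}


def greedy_min_cover(
    candidates: Mapping[str, frozenset[str] | set[str]],
    universe: set[str] | frozenset[str],
    scores: DockingScoreTable | None = None,
    k_used: int = 0,
    min_targets: int = 2,
) -> CocktailPlan:
    """Greedy set cover: smallest drug package covering the protein universe.

    Repeatedly selects the drug covering the most still-uncovered proteins;
    ties break by higher summed docking score over the newly covered
    proteins (when a score table is supplied), then by drug id. Proteins no
    candidate can reach are reported as uncovered, not fatal.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe = frozenset(universe)
    cand = {d: frozenset(ps) & universe for d, ps in candidates.items()}
    cand = {d: ps for d, ps in cand.items() if ps}
    score_of: dict[tuple[str, str], float] = {}
    if scores is not None:
        score_of = {
            (str(r.drug_id), str(r.protein_id)): float(r.score)
            for r in scores.frame.itertuples()
        }
    selected: list[str] = []
    coverage: dict[str, frozenset[str]] = {}
    uncovered = set(universe)
    while uncovered:
        best = None
        for d in sorted(cand):
            if d in coverage:
                continue
            gain = cand[d] & uncovered
            if not gain:
                continue
            tie_score = sum(score_of.get((d, p), 0.0) for p in gain)
            key = (len(gain), tie_score, _NegStr(d))
            if best is None or key > best[0]:
                best = (key, d, gain)
        if best is None:
            break
        _, d, gain = best
        selected.append(d)
        coverage[d] = frozenset(cand[d])
        uncovered -= cand[d]
    covered = frozenset().union(*coverage.values()) if coverage else frozenset()
    return CocktailPlan(
        selected_drugs=tuple(selected),
        coverage=coverage,
        covered_proteins=covered,
        uncovered_proteins=universe - covered,
        k_used=k_used,
        min_targets=min_targets,
    )


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def brute_force_min_cover(
    candidates: Mapping[str, frozenset[str] | set[str]],
    universe: set[str] | frozenset[str],
) -> int:
    """Size of an optimal cover of the coverable part of the universe.

    Exhaustive over all drug subsets; intended as a test oracle for small
    instances (<= ~15 drugs).
    """
    universe = frozenset(universe)
    reachable = frozenset().union(*candidates.values()) & universe if candidates \
        else frozenset()
    drugs = sorted(candidates)
    if len(drugs) > 20:
        raise ValueError("brute force limited to 20 drugs")
    best = len(drugs) + 1
    from itertools import combinations
    for size in range(0, len(drugs) + 1):
        if size >= best:
            break
        for combo in combinations(drugs, size):
            cov = frozenset().union(*(candidates[d] for d in combo)) if combo else frozenset()
            if reachable <= cov:
                best = size
                break
        if best == size:
            break
    return best


def cocktail_report(
    plan: CocktailPlan,
    scores: DockingScoreTable | None = None,
    sums: CRVSumTable | None = None,
) -> dict:
    """JSON-serializable report of a cocktail plan.

    Lists per-drug (protein, score) blocks, coverage statistics and, when
    CRV sums are supplied, the summed CRV of covered vs uncovered proteins.
    """
    score_of: dict[tuple[str, str], float] = {}
    if scores is not None:
        score_of = {
            (str(r.drug_id), str(r.protein_id)): float(r.score)
            for r in scores.frame.itertuples()
        }
    blocks = []
    for d in plan.selected_drugs:
        blocks.append({
            "drug_id": d,
            "targets": [
                {"protein_id": p, "score": score_of.get((d, p))}
                for p in sorted(plan.coverage[d])
            ],
        })
    report = {
        "selected_drugs": list(plan.selected_drugs),
        "blocks": blocks,
        "n_drugs": len(plan.selected_drugs),
        "n_covered": len(plan.covered_proteins),
        "n_uncovered": len(plan.uncovered_proteins),
        "covered_proteins": sorted(plan.covered_proteins),
        "uncovered_proteins": sorted(plan.uncovered_proteins),
        "k_used": plan.k_used,
        "min_targets": plan.min_targets,
    }
    if not plan.selected_drugs:
        report["note"] = "no coverage: no candidate drug covers any universe protein"
    if sums is not None:
        lookup = dict(zip(sums.frame["protein_id"], sums.frame["crv_sum"]))
        report["crv_sum_covered"] = float(
            sum(lookup.get(p, 0.0) for p in plan.covered_proteins))
        report["crv_sum_uncovered"] = float(
            sum(lookup.get(p, 0.0) for p in plan.uncovered_proteins))
    return report


def plan_from_report(report: dict) -> CocktailPlan:
    """Reconstruct a CocktailPlan from a report round-tripped through JSON."""
    coverage = {
        b["drug_id"]: frozenset(t["protein_id"] for t in b["targets"])
        for b in report["blocks"]
    }
    return CocktailPlan(
        selected_drugs=tuple(report["selected_drugs"]),
        coverage=coverage,
        covered_proteins=frozenset(report["covered_proteins"]),
        uncovered_proteins=frozenset(report["uncovered_proteins"]),
        k_used=report["k_used"],
        min_targets=report["min_targets"],
    )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
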