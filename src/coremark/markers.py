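"""Core / specific marker sets and CRV-sum ranking across cancers.

Core network markers are the proteins significant in *every* cancer
studied; a specific marker of cancer k is significant in k and in no other
cancer. Proteins significant in two or more cancers but not all belong to
neither set and are reported in a separate shared-partial bucket.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .types import CRVSumTable, CRVTable, MarkerSets


def core_markers(per_cancer: Mapping[str, Iterable[str]]) -> MarkerSets:
    """Intersect per-cancer significant sets into core and specific markers."""
    if len(per_cancer) < 2:
        raise ValueError("core/specific decomposition needs at least 2 cancers")
    cancer_ids = tuple(sorted(per_cancer))
    sets = {k: frozenset(per_cancer[k]) for k in cancer_ids}
    core = frozenset.intersection(*sets.values())
    specific = {
        k: sets[k] - frozenset().union(*(sets[j] for j in cancer_ids if j != k))
        for k in cancer_ids
    }
    everything = frozenset().union(*sets.values())
    shared_partial = everything - core - frozenset().union(*specific.values())
    return MarkerSets(cancer_ids=cancer_ids, per_cancer_significant=sets,
                      core=core, specific=specific, shared_partial=shared_partial)


def crv_sum_rank(
    tables: Mapping[str, CRVTable],
    proteins: Iterable[str],
) -> CRVSumTable:
    """Sum each protein's CRVs over cancers and rank descending by the sum.

    Every requested protein must be present in every cancer's table; ties
    in the sum are broken lexicographically by protein id and ranks are
    dense (1, 2, 2, 3, ...).
    """
    if not tables:
        raise ValueError("at least one CRV table is required")
    proteins = sorted(set(proteins))
    cancer_ids = sorted(tables)
    per_cancer: dict[str, dict[str, float]] = {}
    for k in cancer_ids:
        t = tables[k]
        lookup = dict(zip(t.protein_ids, map(float, t.crv)))
        missing = [p for p in proteins if p not in lookup]
        if missing:
            raise KeyError(f"proteins missing from cancer {k!r}: {missing}")
        per_cancer[k] = lookup
    rows = []
    for p in proteins:
        crvs = {f"crv_{k}": per_cancer[k][p] for k in cancer_ids}
        rows.append({"protein_id": p, **crvs, "crv_sum": sum(crvs.values())})
    frame = pd.DataFrame(rows).sort_values(
        ["crv_sum", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = frame["crv_sum"].rank(method="dense", ascending=False).astype(int)
    return CRVSumTable(frame=frame)


def top_n_targets(table: CRVSumTable, n: int) -> list[str]:
    """First n protein ids in rank order."""
    return table.top(n)
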