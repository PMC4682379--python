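#!/usr/bin/env python
"""Intersect per-cancer significant proteins into core markers and select a
multi-target cocktail over a synthetic docking table for the core.

Reads the CRV tables under results/, forms core/specific marker sets,
ranks core proteins by summed CRV, generates docking scores with planted
multi-target ligands for the recovered core, and writes the greedy
minimum-cover drug package.
"""

import json
from pathlib import Path

from coremark import io as cio
from coremark.cocktail import (cocktail_report, greedy_min_cover,
                               multi_target_ligands, top_k_ligands, write_report)
from coremark.diffnet import significant_proteins
from coremark.markers import core_markers, crv_sum_rank
from coremark.synthetic import generate_docking_scores

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 7
truth = json.loads((BASE / "simulated" / "truth.json").read_text())

tables, sig = {}, {}
for path in sorted(BASE.glob("crv_*.tsv")):
    cid = path.stem.split("_", 1)[1]
    t = cio.read_crv_table(path, n_permutations=1000, alpha=0.01, seed=SEED,
                           cancer_id=cid)
    tables[cid] = t
    sig[cid] = set(significant_proteins(t))

markers = core_markers(sig)
print(f"core markers (significant in all {len(sig)} cancers): {sorted(markers.core)}")
print(f"planted core: {truth['perturbed_core']}")
for cid, s in sorted(markers.specific.items()):
    print(f"specific to {cid}: {sorted(s)}")

with open(BASE / "markers.json", "w") as fh:
    json.dump({"core": sorted(markers.core),
               "specific": {k: sorted(v) for k, v in sorted(markers.specific.items())},
               "shared_partial": sorted(markers.shared_partial)},
              fh, indent=2, sort_keys=True)
    fh.write("\n")

if markers.core:
    sums = crv_sum_rank(tables, markers.core)
    sums.frame.to_csv(BASE / "core_crv_sum.tsv", sep="\t", index=False)
    scores, planted = generate_docking_scores(sorted(markers.core), n_drugs=60,
                                              n_multi_target=3, targets_per_multi=2,
                                              top_k=20, seed=SEED + 200)
    cio.write_docking_scores(scores, BASE / "docking_scores.csv")
    multi = multi_target_ligands(top_k_ligands(scores, 20), 2)
    plan = greedy_min_cover(multi, set(markers.core), scores=scores,
                            k_used=20, min_targets=2)
    write_report(cocktail_report(plan, scores=scores, sums=sums),
                 BASE / "cocktail_plan.json")
    print(f"cocktail: {len(plan.selected_drugs)} drugs "
          f"({', '.join(plan.selected_drugs)}) cover "
          f"{len(plan.covered_proteins)}/{len(markers.core)} core proteins "
          f"({len(planted)} multi-target ligands were planted)")
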