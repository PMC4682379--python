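"""End-to-end driver: simulate -> infer -> CRV -> markers -> cocktail.

Every artifact is written as plain text under one run directory together
with a JSON metadata side-car carrying the seed, a config hash, and the
tool version, so a rerun with the same configuration is byte-identical
(the append-only ``run.log`` is the one exception: each run appends its
own block).
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as cio
from .cocktail import cocktail_report, greedy_min_cover, multi_target_ligands, top_k_ligands, write_report
from .diffnet import differential_matrix, permutation_pvalues, significant_proteins
from .inference import infer_ppin
from .markers import core_markers, crv_sum_rank
from .synthetic import generate_docking_scores, generate_ground_truth, make_candidate_network, simulate_expression
from .types import RunConfig

logger = logging.getLogger(__name__)

#: default synthetic study: a 40-protein subnetwork at PPI-like sparsity,
#: two cancer types sharing a 2-protein perturbed core plus 1 specific
#: protein each, 400 samples per condition. Sized by power analysis so the
#: planted core is recoverable by the degree-preserving permutation null.
DEFAULT_SCENARIO = dict(
    M=40,
    edge_density=0.15,
    n_cancers=2,
    core_size=2,
    specific_size=1,
    effect_size=0.5,
    noise_sd=0.3,
    n_samples=400,
    fp_edges=20,
    n_drugs=60,
    n_multi_target=3,
    targets_per_multi=2,
)


def run_pipeline(config: RunConfig, out_dir, scenario: dict | None = None) -> dict:
    """Run the full synthetic study and write all artifacts under out_dir.

    Returns a summary dict (planted vs recovered sets, file inventory).
    """
    missing = {name: p for name, p in config.paths.items() if not Path(p).exists()}
    if missing:
        raise FileNotFoundError(f"configured inputs do not exist: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_SCENARIO, **(scenario or {})}
    log_lines: list[str] = [f"run seed={config.seed} config={cio.config_hash(config)}"]

    def stage(name):
        def fail(exc):
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return fail

    # --- simulate ---------------------------------------------------------
    try:
        truth = generate_ground_truth(
            M=params["M"], edge_density=params["edge_density"],
            n_cancers=params["n_cancers"], core_size=params["core_size"],
            specific_size=params["specific_size"], effect_size=params["effect_size"],
            noise_sd=params["noise_sd"], seed=config.seed,
        )
        candidate, labels = make_candidate_network(truth, params["fp_edges"],
                                                   seed=config.seed + 1)
        cancer_ids = sorted(truth.A_cancer_per_type)
        exprs = {}
        sub = 2
        for cid in cancer_ids:
            exprs[(cid, "normal")] = simulate_expression(
                truth.A_normal, params["n_samples"], params["noise_sd"],
                seed=config.seed + sub, protein_ids=truth.protein_ids,
                condition="normal", cancer_id=cid)
            exprs[(cid, "cancer")] = simulate_expression(
                truth.A_cancer_per_type[cid], params["n_samples"], params["noise_sd"],
                seed=config.seed + sub + 1, protein_ids=truth.protein_ids,
                condition="cancer", cancer_id=cid)
            sub += 2
        cio.write_edge_list(candidate, out / "candidate_network.tsv")
        for (cid, cond), e in exprs.items():
            cio.write_expression(e, out / f"expression_{cid}_{cond}.tsv")
        log_lines.append(
            f"simulate: {params['M']} proteins, {len(candidate)} candidate edges "
            f"({params['fp_edges']} planted false), {len(cancer_ids)} cancers")
    except Exception as exc:  # noqa: BLE001
        stage("simulate")(exc)

    # --- infer ------------------------------------------------------------
    try:
        nets = {key: infer_ppin(e, candidate, config) for key, e in exprs.items()}
        for (cid, cond), m in nets.items():
            cio.write_interaction_matrix(m, out / f"ppin_{cid}_{cond}.tsv")
        n_edges = {key: int((m.A != 0).sum() // 2) for key, m in nets.items()}
        log_lines.append(f"infer: retained edges per network {sorted(n_edges.items())}")
    except Exception as exc:  # noqa: BLE001
        stage("infer")(exc)

    # --- crv --------------------------------------------------------------
    try:
        crv_tables = {}
        for i, cid in enumerate(cancer_ids):
            diff = differential_matrix(nets[(cid, "cancer")], nets[(cid, "normal")])
            crv_tables[cid] = permutation_pvalues(
                diff, n_permutations=config.n_permutations,
                alpha=config.alpha_crv, seed=config.seed + 100 + i)
            cio.write_crv_table(crv_tables[cid], out / f"crv_{cid}.tsv")
        sig = {cid: significant_proteins(t) for cid, t in crv_tables.items()}
        log_lines.append(f"crv: significant per cancer "
                         f"{[(cid, len(s)) for cid, s in sorted(sig.items())]}")
    except Exception as exc:  # noqa: BLE001
        stage("crv")(exc)

    # --- core markers and ranking ----------------------------------------
    try:
        markers = core_markers(sig)
        sums = crv_sum_rank(crv_tables, markers.core) if markers.core else None
        import json
        with open(out / "markers.json", "w") as fh:
            json.dump({
                "core": sorted(markers.core),
                "specific": {k: sorted(v) for k, v in sorted(markers.specific.items())},
                "shared_partial": sorted(markers.shared_partial),
                "planted_core": sorted(truth.perturbed_core),
                "planted_specific": {k: sorted(v) for k, v in
                                     sorted(truth.perturbed_specific.items())},
            }, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if sums is not None:
            sums.frame.to_csv(out / "crv_sum_rank.tsv", sep="\t", index=False)
        log_lines.append(f"core: {len(markers.core)} core, "
                         f"planted {len(truth.perturbed_core)}")
    except Exception as exc:  # noqa: BLE001
        stage("core")(exc)

    # --- cocktail ---------------------------------------------------------
    try:
        universe = set(markers.core) or set(truth.perturbed_core)
        scores, planted_drugs = generate_docking_scores(
            sorted(universe), n_drugs=params["n_drugs"],
            n_multi_target=params["n_multi_target"],
            targets_per_multi=min(params["targets_per_multi"], max(len(universe), 2)),
            top_k=config.top_k, seed=config.seed + 200)
        cio.write_docking_scores(scores, out / "docking_scores.csv")
        shortlists = top_k_ligands(scores, config.top_k)
        multi = multi_target_ligands(shortlists, config.min_targets)
        candidates = multi if multi else {
            d: ps for d, ps in multi_target_ligands(shortlists, 1).items()}
        plan = greedy_min_cover(candidates, universe, scores=scores,
                                k_used=config.top_k, min_targets=config.min_targets)
        report = cocktail_report(plan, scores=scores, sums=sums)
        write_report(report, out / "cocktail_plan.json")
        log_lines.append(f"cocktail: {len(plan.selected_drugs)} drugs cover "
                         f"{len(plan.covered_proteins)}/{len(universe)} proteins")
    except Exception as exc:  # noqa: BLE001
        stage("cocktail")(exc)

    cio.write_metadata(config, out / "run_metadata.json",
                       extra={"scenario": {k: params[k] for k in sorted(params)}})
    with open(out / "run.log", "a") as fh:
        for line in log_lines:
            fh.write(line + "\n")

    return {
        "planted_core": frozenset(truth.perturbed_core),
        "recovered_core": frozenset(markers.core),
        "planted_specific": {k: frozenset(v) for k, v in truth.perturbed_specific.items()},
        "recovered_specific": {k: frozenset(v) for k, v in markers.specific.items()},
        "significant_per_cancer": {k: tuple(v) for k, v in sig.items()},
        "plan": plan,
        "planted_drugs": planted_drugs,
        "out_dir": str(out),
    }
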