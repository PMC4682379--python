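# coremark

Identification of **common core network markers** of multiple cancers from
expression data, and selection of **multi-target drug cocktails** against
them.

Cancers differ in their mutations but share rewired protein–protein
interaction (PPI) machinery. `coremark` implements a systems-biology
pipeline that finds the shared rewiring: for each cancer type it infers a
cancer and a normal PPI network from expression data constrained to a
candidate interaction set, scores every protein's interaction change with
a **carcinogenesis relevance value (CRV)**, keeps the proteins whose CRV is
significant under a degree-preserving permutation null, and intersects the
per-cancer significant sets into core network markers. A docking-score
module then picks a minimal package of ligands that jointly hit the core —
multi-target therapy rather than single-target inhibition.

## The model in brief

Each protein `i` is fit against its candidate interactors,

```
x_i[n] = Σ_j α_ij · x_j[n] + w_i[n]
```

by least squares (the Gaussian MLE); false-positive interactions are
pruned per protein by forward-stepwise AIC, `AIC(S) = n·ln(RSS/n) + 2|S|`,
followed by coefficient t-tests, and the directed estimates are
symmetrized by keeping the larger-magnitude direction. For cancer type `k`
the differential network is `D^k = A_C^k − A_N^k` and

```
CRV_i^k = Σ_{j≠i} |d_ij^k| ,
```

with an empirical p-value from rewiring `D`'s support graph by double-edge
swaps (every protein keeps its number of changed interactions) and
carrying the observed weights onto the rewired edges. Proteins with
`p ≤ 0.01` in *every* cancer are the core markers. Docking scores are
consumed (never computed): per-protein top-k shortlists, redundancy
analysis (drugs shortlisted by ≥ 2 proteins), and a greedy minimum set
cover yield the cocktail.

Because the study's microarray inputs are not redistributable, the package
ships a first-class synthetic-data generator (`coremark.synthetic`) that
emulates all three inputs — expression from the linear association model,
candidate networks with planted false edges, docking tables with planted
multi-target ligands — so every stage is testable end to end. See
`docs/methods.md` for the full model, design choices, and known
limitations.

## Worked example

Run the full synthetic study — simulate, infer four networks, permutation
CRVs, marker intersection, cocktail — in one call:

```bash
coremark run --seed 7 --out run7
```

which prints

```
recovered core ['P004', 'P023'] (planted ['P004', 'P023'])
```

the planted two-protein core recovered exactly from the expression data
alone. The run directory holds every artifact as plain text: expression
matrices, the candidate network, inferred interaction matrices, per-cancer
CRV tables, `markers.json`, and `cocktail_plan.json`.

The same stages are available as numbered drivers under `analysis/`; the
first recomputes the published-table arithmetic:

```bash
python analysis/01_published_tables.py
```

```
top 5 targets: UBC, TP53, KIAA0101, HDAC1, CDK2
UBC dominates with a summed CRV of 496.3222 (next: TP53 at 79.4445)
redundancy analysis: 13 multi-target ligands cover 11 of the 28 core
proteins; a greedy package of 7 drugs suffices for those 11
```

UBC's summed CRV (496.32 across bladder, liver, colorectal and lung
cancer) is six times the runner-up's — ubiquitin C sits at the centre of
the shared rewiring — and of 13 ligands that dock into the top-20 lists of
two or more core proteins, a greedy cover needs only 7 to hit all 11
reachable targets. Scripts `02`–`05` then run the synthetic study
stage by stage (`02` simulate → `03` infer → `04` CRV → `05` markers +
cocktail), writing tables under `results/`.

Individual stages are also exposed as subcommands
(`coremark simulate | infer | crv | core | rank | cocktail`), each reading
and writing plain TSV/CSV/JSON.

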