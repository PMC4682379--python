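# Methods

## The model

Each protein `i` in a candidate interaction network is described by a
linear protein association model over its candidate interactors `M_i`:

    x_i[n] = sum_{j in M_i} alpha_ij * x_j[n] + w_i[n],

where `x_i[n]` is the expression of protein `i` in sample `n`, `alpha_ij`
is the (dimensionless) association ability between proteins `i` and `j`,
and `w_i[n]` is Gaussian noise. Samples are exchangeable; there is no
intercept, so expression rows are mean-centered per protein before fitting.
Under Gaussian noise the maximum-likelihood estimate of the coefficient
vector is ordinary least squares, and the ML residual variance is `RSS/n`.

False-positive candidate interactions are pruned per protein in two steps:

1. **AIC order selection.** `AIC(S) = n·ln(RSS_S/n) + 2|S|`, minimized by
   forward-stepwise search from the empty model: at each step the candidate
   giving the largest AIC decrease is added (ties broken by candidate id);
   the search stops when no addition decreases AIC. An exhaustive search
   over all subsets is available for up to 15 candidates and is used as the
   oracle in the test suite.
2. **Coefficient t-tests.** Survivors are refit and candidates with a
   two-sided coefficient p-value above `alpha_t` (default 0.05) are
   dropped, then the final model is refit on the remainder.

The two directed estimates of each pair are reconciled into one symmetric
interaction matrix by keeping the estimate of larger absolute value (its
sign retained); a pair estimated in only one direction is mirrored. Every
interaction matrix is exactly symmetric with zero diagonal, and nonzero
only on candidate pairs.

## Differential network and CRV

For each cancer type the differential network is `D = A_cancer − A_normal`.
The carcinogenesis relevance value of protein `i` is the absolute row sum

    CRV_i = sum_{j != i} |d_ij|,

the total change in interaction ability of protein `i` between conditions.
The absolute value matters: without it, a protein whose interactions move
in opposite directions could cancel to a CRV of zero.

Significance is assessed with a degree-preserving permutation null: the
support graph of `D` is rewired by repeated double-edge swaps (default 4×
the edge count of attempted swaps per draw), so every protein keeps its
number of changed interactions, and the observed edge weights are carried
onto the rewired edges in seeded shuffled order. CRVs are recomputed per
draw, and

    p_i = (1 + #{draws: CRV_i^perm >= CRV_i^obs}) / (1 + N).

The add-one form keeps p-values in `[1/(N+1), 1]`; at the default N=1000 —
or the published-scale N=100,000, available via `n_permutations` — the
difference from the raw fraction is negligible. Proteins with `p <= 0.01`
are significant. Core network markers are the proteins significant in
every cancer studied; a specific marker is significant in exactly one
cancer; proteins significant in two or more cancers but not all are
reported in a separate shared-partial bucket (they are neither core nor
specific).

A structural property of this null worth knowing: a support graph that
admits no legal double-edge swap (a star, for instance) cannot be rewired,
so the hub of a star has a permuted CRV identical to its observed CRV and
a p-value of 1 regardless of how much weight it carries. More generally,
perturbations on proteins of support-degree 2–3 are near-undetectable at
`alpha = 0.01`: a null draw needs only two or three lucky weight
assignments to tie them, putting a floor of roughly 0.03–0.06 on their
attainable p-values. The permutation null measures *concentration* of
change on a protein relative to its connectivity, and low-degree nodes
offer nothing to concentrate.

## Cocktail selection

Docking scores are consumed, never computed. Per protein, the top-k
(default 20) highest-scoring drugs form a shortlist (score ties break by
drug id). Redundancy analysis returns the drugs shortlisted by at least
`min_targets` (default 2) distinct proteins. The minimum drug package is a
classic greedy set cover over those multi-target candidates: repeatedly
pick the drug covering the most still-uncovered proteins, breaking ties by
higher summed docking score over the newly covered proteins and then by
drug id. Scores are never compared across proteins except in that
tie-break — docking scores from different binding sites are not calibrated
against each other. Proteins reachable by no candidate are reported as
uncovered rather than failing the run.

Greedy set cover carries the standard `(1 + ln|universe|)`-factor
guarantee but is not exact in general; on the suite's random covering
instances it matches the exhaustive optimum about 93–96% of the time. An
exhaustive optimizer (`brute_force_min_cover`) is provided for instances
up to 20 drugs and serves as the oracle in tests.

## Synthetic data generator

The generator emulates the study's three inputs. Expression is sampled
from the simultaneous system `x = A x + w`: a sample is the unique
solution `x = (I − A)^{-1} w` with `w` i.i.d. Gaussian
(`noise_sd`, default 0.3), which exists whenever the spectral radius of
`A` is below one. Edge weights are drawn uniform on `±[0.2, 0.8]` over an
Erdős–Rényi support and the base matrix is rescaled to spectral radius
0.95 when needed.

Perturbations: each cancer's matrix equals the normal matrix except on
rows/columns of its perturbed proteins (a core set shared by all cancers
plus per-cancer specific sets), whose incident edge weights are shifted by
`effect_size` (default 0.5) *against* the sign of the normal weight — a
weakening/reversal of the normal interaction. Two alternatives were
examined and rejected: random shift signs occasionally cancel a weight to
near zero, whereupon pruning removes the edge in the cancer condition and
the differential entry halves; coherent strengthening inflates the
spectral radius so much that the joint stability rescale (applied to *all*
matrices, preserving perturbation locality; the factor is recorded on the
scenario) shrinks every effect by ~2×. The reversal rule keeps the
differential entry at exactly `effect_size` on every perturbed edge with
only a mild joint rescale. Perturbed proteins are drawn among nodes of
degree ≥ 4, mirroring the hub-like character of published network markers
and the identifiability boundary of the permutation null described above.

Candidate networks are the true edge union plus a chosen number of planted
false-positive pairs, with labels retained for evaluation. Docking tables
plant a chosen number of multi-target ligands whose scores for their
targets sit in the top tenth of the score range; background drugs dock to
single proteins, and every protein receives at least top-k entries.

What the generator does **not** emulate: microarray intensity
distributions, probe/gene mapping, normalization or batch structure,
heavy-tailed noise, and any directionality of regulation. Passing tests
therefore demonstrate the statistical machinery under the model's own
assumptions, not robustness to real microarray artifacts.

## Study scenarios and sample sizes

The original microarray sample sizes are not stated anywhere usable, so
scenario sizes here are the package's own design, chosen by power analysis
on seed blocks disjoint from any test seed and then frozen:

- **Default pipeline demo:** M=40 proteins, density 0.15, two cancers,
  core 2 + one specific protein per cancer, n=400 samples/condition,
  20 planted false edges, N=1000 permutations.
- **Detection power study:** M=40, density 0.15, core 3, n=200/condition
  (sensitivity 1.0, FPR 0.0 over 20 replicates).
- **Null calibration:** M=20, density 0.15, n=100/condition, 50
  replicates (fraction flagged at p≤0.01 ≈ 0.016–0.018).
- **Edge-pruning evaluation:** M=30, density 0.1, 20 planted false edges,
  n=200 (true-edge retention ≈ 0.99, false-edge pruning ≈ 0.77–0.92
  across seeds).
- **Coefficient recovery:** M=20, density 0.2, n=1000, noise 0.1.

## Known limitations

Two deserve emphasis because they are properties of the model, not bugs:

1. **Simultaneity bias.** Data generated from the simultaneous system make
   per-protein least squares inconsistent for `A`: the regressors `x_j`
   are correlated with the target's own noise through the system solve.
   For a single symmetric edge `a` the OLS estimand is `2a/(1+a²)` —
   first-order bias of order `|a|` itself. Retained coefficients
   accordingly over-estimate planted weights with a mean absolute error
   near 0.09–0.10 at the default weight scale, at any sample size. The
   differential analysis is largely immune (both conditions are biased the
   same way, and the difference of estimands preserves the perturbation up
   to second-order terms), which is why marker detection works while
   point recovery of `alpha` does not.
2. **Markov blanket of the simultaneous model.** The conditional
   independence graph of `x = (I−A)^{-1} w` is the support of `A²`, not of
   `A`: proteins two hops apart have genuinely nonzero partial
   correlations. Planted "false" candidate edges between such pairs are
   therefore sometimes retained by a correctly working fit, which bounds
   edge-pruning specificity near 0.8 at realistic densities.

Other limitations: forward-stepwise AIC can diverge from the exhaustive
optimum on unfavourable draws (~0–6% of random instances; the exhaustive
flag exists for small candidate sets); collinear candidates are rejected
with a named error rather than regularized; no FDR control beyond the
fixed p≤0.01 rule; greedy cover is approximate (see above); and all
matrices must fit in memory (the intended scale is hundreds of proteins,
not proteome-wide).

## Numerical conventions

Exact-fit RSS is floored at the smallest positive double inside the AIC
logarithm. Rank deficiency is detected on the Gram matrix at a relative
1e-10 tolerance. Permutation exceedance counts use a 1e-12 absolute
tolerance so float round-off in row sums cannot turn a tie into a
non-exceedance. All randomness flows through `numpy.random.default_rng`
seeds carried in configs and recorded in artifacts; reruns with the same
config are byte-identical (the append-only run log aside). Ranking ties
break lexicographically by identifier everywhere, making every ordering
deterministic.
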