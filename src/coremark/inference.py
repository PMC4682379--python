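"""Per-protein association-model fitting and interaction-matrix assembly.

Each protein i in the candidate network is modelled as a linear combination
of its candidate interactors,

    x_i[n] = sum_j alpha_ij x_j[n] + w_i[n],

with no intercept; expression rows are mean-centered per protein before
fitting so scale offsets do not leak into the coefficients. Under Gaussian
noise the maximum-likelihood estimate of alpha is the ordinary
least-squares solution and the ML residual variance is RSS/n, which gives
the AIC dialect used for order selection:

    AIC(S) = n * ln(RSS_S / n) + 2 |S|.

False-positive interactions are pruned per protein by forward-stepwise AIC
followed by a two-sided t-test on each surviving coefficient; the two
directed estimates of a pair are then reconciled by keeping the one of
larger absolute value.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
from scipy import stats

from .types import (
    AssociationFit,
    Edge,
    ExpressionMatrix,
    InteractionMatrix,
    RunConfig,
    canonical_edge,
)

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


class CollinearityError(ValueError):
    """Design matrix is rank-deficient; names the offending candidates."""


def _centered(expr: ExpressionMatrix) -> np.ndarray:
    return expr.values - expr.values.mean(axis=1, keepdims=True)


def _ols(X: np.ndarray, y: np.ndarray, names: tuple[str, ...]):
    """No-intercept OLS: coefficients, RSS, and two-sided coefficient p-values."""
    n, k = X.shape
    if k == 0:
        return np.empty(0), float(y @ y), np.empty(0)
    gram = X.T @ X
    rank = np.linalg.matrix_rank(gram, tol=_RANK_TOL * max(1.0, float(np.abs(gram).max())))
    if rank < k:
        # identify a minimal set of columns involved in the dependency
        bad = []
        for i in range(k):
            sub = np.delete(np.arange(k), bad + [i])
            if np.linalg.matrix_rank(X[:, sub]) == np.linalg.matrix_rank(X[:, np.delete(np.arange(k), bad)]):
                bad.append(i)
        culprits = [names[i] for i in bad] or list(names)
        raise CollinearityError(f"collinear candidates for this target: {culprits}")
    coef = np.linalg.solve(gram, X.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - k
    if dof <= 0:
        raise ValueError(f"too few samples: n={n} with {k} candidates leaves no degrees of freedom")
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(np.linalg.inv(gram)), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.where(se > 0, pvals, 0.0)
    return coef, rss, pvals


def fit_association_model(
    expr: ExpressionMatrix,
    target: str,
    candidates: list[str],
) -> AssociationFit:
    """Least-squares fit of one protein on its candidate interactors.

    Residual variance is the maximum-likelihood RSS/n; p-values are
    classical two-sided coefficient t-tests (df = n - k).
    """
    if target in candidates:
        raise ValueError(f"target {target!r} cannot be its own candidate")
    missing = [p for p in [target, *candidates] if p not in expr.protein_ids]
    if missing:
        raise KeyError(f"proteins absent from expression matrix: {missing}")
    n = expr.n_samples
    if candidates and n <= len(candidates) + 1:
        raise ValueError(
            f"n_samples={n} insufficient for {len(candidates)} candidates "
            f"(need n > k + 1)"
        )
    centered = _centered(expr)
    idx = {p: i for i, p in enumerate(expr.protein_ids)}
    y = centered[idx[target]]
    X = centered[[idx[c] for c in candidates]].T if candidates else np.empty((n, 0))
    coef, rss, pvals = _ols(X, y, tuple(candidates))
    return AssociationFit(
        target=target,
        candidates=tuple(candidates),
        retained=tuple(candidates),
        coefficients=coef,
        coefficient_pvalues=dict(zip(candidates, map(float, pvals))),
        residual_variance=rss / n,
    )


def aic_value(rss: float, n: int, k: int) -> float:
    """AIC(S) = n ln(RSS/n) + 2k; RSS floored at machine tiny for exact fits."""
    return n * math.log(max(rss, np.finfo(float).tiny) / n) + 2 * k


def _subset_rss(centered: np.ndarray, idx: dict[str, int], target: str,
                subset: tuple[str, ...]) -> float:
    y = centered[idx[target]]
    if not subset:
        return float(y @ y)
    X = centered[[idx[c] for c in subset]].T
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def aic_order_select(
    expr: ExpressionMatrix,
    target: str,
    candidates: list[str],
    exhaustive: bool = False,
) -> tuple[tuple[str, ...], tuple[tuple[int, float], ...]]:
    """Choose the retained interactor subset by minimizing AIC.

    Default search is forward stepwise from the empty model, adding the
    candidate giving the largest AIC decrease (ties broken by candidate
    id) and stopping when no addition decreases AIC. With
    ``exhaustive=True`` (allowed up to 15 candidates) every subset is
    scored and the global minimizer returned.
    Returns ``(retained, trace)`` with the trace of (size, AIC) visited.
    """
    if target in candidates:
        raise ValueError(f"target {target!r} cannot be its own candidate")
    missing = [p for p in [target, *candidates] if p not in expr.protein_ids]
    if missing:
        raise KeyError(f"proteins absent from expression matrix: {missing}")
    n = expr.n_samples
    if candidates and n <= len(candidates) + 1:
        raise ValueError(f"n_samples={n} insufficient for {len(candidates)} candidates")
    centered = _centered(expr)
    idx = {p: i for i, p in enumerate(expr.protein_ids)}

    if exhaustive:
        if len(candidates) > 15:
            raise ValueError("exhaustive search limited to 15 candidates")
        best: tuple[str, ...] = ()
        best_aic = aic_value(_subset_rss(centered, idx, target, ()), n, 0)
        trace = [(0, best_aic)]
        for k in range(1, len(candidates) + 1):
            for subset in combinations(sorted(candidates), k):
                a = aic_value(_subset_rss(centered, idx, target, subset), n, k)
                trace.append((k, a))
                # ties resolve to the first subset in (size, lexicographic) order
                if a < best_aic:
                    best, best_aic = subset, a
        return best, tuple(trace)

    current: tuple[str, ...] = ()
    current_aic = aic_value(_subset_rss(centered, idx, target, ()), n, 0)
    trace = [(0, current_aic)]
    remaining = sorted(candidates)
    while remaining:
        scored = [
            (aic_value(_subset_rss(centered, idx, target, current + (c,)), n,
                       len(current) + 1), c)
            for c in remaining
        ]
        best_aic_step, best_c = min(scored)  # ties -> lexicographically first id
        if best_aic_step >= current_aic:
            break
        current = tuple(sorted(current + (best_c,)))
        current_aic = best_aic_step
        remaining.remove(best_c)
        trace.append((len(current), current_aic))
    return current, tuple(trace)


def coefficient_ttest(fit: AssociationFit, alpha: float = 0.05) -> tuple[str, ...]:
    """Drop retained candidates whose coefficient p-value exceeds alpha."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return tuple(c for c in fit.retained if fit.coefficient_pvalues[c] <= alpha)


def prune_association_model(
    expr: ExpressionMatrix,
    target: str,
    candidates: list[str],
    alpha_t: float = 0.05,
    exhaustive: bool = False,
) -> AssociationFit:
    """Full per-protein pruning: AIC order selection, then coefficient t-tests.

    The final coefficients are refit on the survivors so the reported
    estimates correspond to the model actually retained.
    """
    retained, trace = aic_order_select(expr, target, candidates, exhaustive=exhaustive)
    fit = fit_association_model(expr, target, list(retained))
    survivors = coefficient_ttest(fit, alpha=alpha_t)
    if survivors != fit.retained:
        fit = fit_association_model(expr, target, list(survivors))
    return AssociationFit(
        target=target,
        candidates=tuple(candidates),
        retained=fit.retained,
        coefficients=fit.coefficients,
        coefficient_pvalues=fit.coefficient_pvalues,
        residual_variance=fit.residual_variance,
        aic_trace=trace,
    )


def build_interaction_matrix(
    fits: list[AssociationFit],
    protein_ids: list[str],
    condition: str = "normal",
    cancer_id: str = "",
) -> InteractionMatrix:
    """Symmetrize directed per-protein estimates into one interaction matrix.

    When the two directed estimates of a pair disagree, the one of larger
    absolute value is used for both entries (its sign kept); a pair
    estimated in only one direction is mirrored; pairs pruned in both
    directions are zero.
    """
    seen = set()
    for f in fits:
        if f.target in seen:
            raise ValueError(f"duplicate fit for target {f.target!r}")
        seen.add(f.target)
    idx = {p: i for i, p in enumerate(protein_ids)}
    unknown = [f.target for f in fits if f.target not in idx]
    if unknown:
        raise KeyError(f"fit targets absent from protein_ids: {unknown}")
    M = len(protein_ids)
    directed = np.zeros((M, M))
    estimated = np.zeros((M, M), dtype=bool)
    for f in fits:
        i = idx[f.target]
        for c, a in zip(f.retained, f.coefficients):
            j = idx[c]
            if i == j:
                continue
            directed[i, j] = a
            estimated[i, j] = True
    A = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            if estimated[i, j] and estimated[j, i]:
                val = directed[i, j] if abs(directed[i, j]) >= abs(directed[j, i]) \
                    else directed[j, i]
            elif estimated[i, j]:
                val = directed[i, j]
            elif estimated[j, i]:
                val = directed[j, i]
            else:
                continue
            A[i, j] = A[j, i] = val
    return InteractionMatrix(protein_ids=tuple(protein_ids), A=A,
                             condition=condition, cancer_id=cancer_id)


def infer_ppin(
    expr: ExpressionMatrix,
    candidate_network: frozenset[Edge] | set[Edge],
    config: RunConfig | None = None,
    exhaustive: bool = False,
) -> InteractionMatrix:
    """Infer a refined interaction matrix from expression and a candidate net.

    Candidates of protein i are its neighbours in the candidate network;
    each protein is fit, pruned (AIC then t-test) and the directed
    estimates symmetrized.
    """
    config = config or RunConfig()
    ids = expr.protein_ids
    known = set(ids)
    for a, b in candidate_network:
        if a not in known or b not in known:
            raise KeyError(f"candidate edge ({a}, {b}) references unknown protein")
    if not candidate_network:
        logger.warning("empty candidate network: returning zero interaction matrix")
        return InteractionMatrix(protein_ids=ids, A=np.zeros((len(ids), len(ids))),
                                 condition=expr.condition, cancer_id=expr.cancer_id)
    neighbours: dict[str, list[str]] = {p: [] for p in ids}
    for a, b in sorted(candidate_network):
        neighbours[a].append(b)
        neighbours[b].append(a)
    fits = [
        prune_association_model(expr, p, sorted(neighbours[p]),
                                alpha_t=config.alpha_t, exhaustive=exhaustive)
        for p in ids if neighbours[p]
    ]
    return build_interaction_matrix(fits, list(ids), condition=expr.condition,
                                    cancer_id=expr.cancer_id)
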