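"""Core data containers for the differential-network marker pipeline.

All matrices are proteins-in-rows; protein identifiers are case-sensitive
strings and are never normalized. Association strengths (``alpha``) are
dimensionless regression coefficients of the linear protein association
model; expression values are on an arbitrary log-intensity-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Undirected edge as a sorted tuple; rejects self-loops."""
    if a == b:
        raise ValueError(f"self-loop on {a!r} is not a valid interaction")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Protein x sample expression values for one condition of one cancer."""

    protein_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_proteins, n_samples)
    condition: str = "normal"  # "cancer" | "normal"
    cancer_id: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = sorted({p for p in self.protein_ids if list(self.protein_ids).count(p) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value at protein "
                f"{self.protein_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        if self.condition not in ("cancer", "normal"):
            raise ValueError(f"condition must be 'cancer' or 'normal', got {self.condition!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.protein_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class AssociationFit:
    """Result of fitting and pruning one protein's association model."""

    target: str
    candidates: tuple[str, ...]
    retained: tuple[str, ...]
    coefficients: np.ndarray  # aligned with `retained`
    coefficient_pvalues: dict[str, float]
    residual_variance: float
    aic_trace: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (len(self.retained),):
            raise ValueError("one coefficient per retained candidate required")
        if not set(self.retained) <= set(self.candidates):
            raise ValueError("retained must be a subset of candidates")
        if self.residual_variance < 0:
            raise ValueError("residual variance must be non-negative")
        object.__setattr__(self, "coefficients", coefs)

    def coefficient(self, candidate: str) -> float:
        """Estimated association strength for a retained candidate, else 0."""
        try:
            return float(self.coefficients[self.retained.index(candidate)])
        except ValueError:
            return 0.0


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric association-strength matrix A for one condition."""

    protein_ids: tuple[str, ...]
    A: np.ndarray
    condition: str = "normal"
    cancer_id: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        m = len(self.protein_ids)
        if A.shape != (m, m):
            raise ValueError(f"A must be {m}x{m}, got {A.shape}")
        if not np.array_equal(A, A.T):
            raise ValueError("interaction matrix must be exactly symmetric")
        if np.any(np.diag(A) != 0.0):
            raise ValueError("interaction matrix must have zero diagonal")
        object.__setattr__(self, "A", A)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.protein_ids)
        return pd.DataFrame(self.A, index=ids, columns=ids)


@dataclass(frozen=True)
class DifferentialNetwork:
    """D = A_cancer - A_normal; entries d_ij are per-pair interaction changes."""

    protein_ids: tuple[str, ...]
    D: np.ndarray
    cancer_id: str = ""

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        m = len(self.protein_ids)
        if D.shape != (m, m):
            raise ValueError(f"D must be {m}x{m}, got {D.shape}")
        if not np.array_equal(D, D.T):
            raise ValueError("differential matrix must be exactly symmetric")
        if np.any(np.diag(D) != 0.0):
            raise ValueError("differential matrix must have zero diagonal")
        object.__setattr__(self, "D", D)


@dataclass(frozen=True)
class CRVTable:
    """Per-protein carcinogenesis relevance values with permutation p-values."""

    protein_ids: tuple[str, ...]
    crv: np.ndarray
    pvalue: np.ndarray
    n_permutations: int
    alpha: float
    seed: int
    cancer_id: str = ""

    def __post_init__(self):
        crv = np.asarray(self.crv, dtype=float)
        p = np.asarray(self.pvalue, dtype=float)
        m = len(self.protein_ids)
        if crv.shape != (m,) or p.shape != (m,):
            raise ValueError("crv and pvalue must be vectors over protein_ids")
        if np.any(crv < 0):
            raise ValueError("CRV values are non-negative by construction")
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        object.__setattr__(self, "crv", crv)
        object.__setattr__(self, "pvalue", p)

    @property
    def significant(self) -> np.ndarray:
        return self.pvalue <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein_id": list(self.protein_ids),
            "crv": self.crv,
            "pvalue": self.pvalue,
            "significant": self.significant,
        })


@dataclass(frozen=True)
class MarkerSets:
    """Core (shared by all cancers) and cancer-specific significant proteins.

    Proteins significant in two or more cancers but not all fall into
    ``shared_partial`` -- they are neither core nor specific.
    """

    cancer_ids: tuple[str, ...]
    per_cancer_significant: dict[str, frozenset[str]]
    core: frozenset[str]
    specific: dict[str, frozenset[str]]
    shared_partial: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CRVSumTable:
    """Per-protein CRVs across cancers with summed CRV and dense rank."""

    frame: pd.DataFrame  # columns: protein_id, crv_<cancer>..., crv_sum, rank

    def top(self, n: int) -> list[str]:
        if n <= 0:
            raise ValueError("n must be positive")
        if n > len(self.frame):
            raise ValueError(f"n={n} exceeds table size {len(self.frame)}")
        return list(self.frame["protein_id"].iloc[:n])


@dataclass(frozen=True)
class DockingScoreTable:
    """(drug, protein, score) records from a virtual-screening run."""

    frame: pd.DataFrame  # columns: drug_id, protein_id, score

    def __post_init__(self):
        df = self.frame
        required = ["drug_id", "protein_id", "score"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if df.duplicated(subset=["drug_id", "protein_id"]).any():
            dupes = df[df.duplicated(subset=["drug_id", "protein_id"], keep=False)]
            pairs = sorted(set(zip(dupes["drug_id"].astype(str), dupes["protein_id"].astype(str))))
            raise ValueError(f"duplicate (drug, protein) pairs: {pairs[:5]}")
        if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
            raise ValueError("docking scores must be finite")

    @property
    def proteins(self) -> list[str]:
        return sorted(self.frame["protein_id"].astype(str).unique())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.frame["drug_id"].astype(str).unique())


@dataclass(frozen=True)
class CocktailPlan:
    """A selected multi-target ligand package and what it covers."""

    selected_drugs: tuple[str, ...]
    coverage: dict[str, frozenset[str]]
    covered_proteins: frozenset[str]
    uncovered_proteins: frozenset[str]
    k_used: int
    min_targets: int

    def __post_init__(self):
        union = frozenset().union(*self.coverage.values()) if self.coverage else frozenset()
        if union != self.covered_proteins:
            raise ValueError("covered_proteins must equal the union of coverage sets")
        if self.covered_proteins & self.uncovered_proteins:
            raise ValueError("covered and uncovered protein sets overlap")
        if any(len(s) == 0 for s in self.coverage.values()):
            raise ValueError("every selected drug must cover at least one protein")


@dataclass(frozen=True)
class GroundTruthScenario:
    """Planted association structure shared by a normal and K cancer conditions."""

    protein_ids: tuple[str, ...]
    A_normal: np.ndarray
    A_cancer_per_type: dict[str, np.ndarray]
    perturbed_core: frozenset[str]
    perturbed_specific: dict[str, frozenset[str]]
    noise_sd: float
    seed: int
    rescale_factor: float = 1.0  # 1.0 when no stability rescaling was needed

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        ids = set(self.protein_ids)
        if not self.perturbed_core <= ids:
            raise ValueError("perturbed_core must be a subset of protein_ids")
        for k, spec in self.perturbed_specific.items():
            if spec & self.perturbed_core:
                raise ValueError(f"specific set of {k} overlaps the core")
        for name, A in [("A_normal", self.A_normal),
                        *self.A_cancer_per_type.items()]:
            A = np.asarray(A, dtype=float)
            if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")
            rho = max(abs(np.linalg.eigvals(A)))
            if rho >= 1.0:
                raise ValueError(f"{name} spectral radius {rho:.3f} >= 1")

    def true_edges(self) -> frozenset[Edge]:
        """Nonzero pairs in the normal or any cancer condition."""
        mask = np.asarray(self.A_normal) != 0
        for A in self.A_cancer_per_type.values():
            mask |= np.asarray(A) != 0
        ids = self.protein_ids
        return frozenset(
            canonical_edge(ids[i], ids[j])
            for i, j in zip(*np.nonzero(np.triu(mask, k=1)))
        )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults follow the study design."""

    seed: int = 0
    alpha_crv: float = 0.01
    alpha_t: float = 0.05
    n_permutations: int = 1000
    top_k: int = 20
    min_targets: int = 2
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, level in [("alpha_crv", self.alpha_crv), ("alpha_t", self.alpha_t)]:
            if not (0 < level < 1):
                raise ValueError(f"{name} must be in (0, 1), got {level}")
        for name, n in [("n_permutations", self.n_permutations),
                        ("top_k", self.top_k), ("min_targets", self.min_targets)]:
            if int(n) < 1:
                raise ValueError(f"{name} must be a positive integer, got {n}")
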