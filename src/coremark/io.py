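"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices and interaction matrices travel as TSV (proteins in
rows), candidate networks as two-column TSV or SIF ("A pp B"), docking
scores as CSV, and run metadata as JSON side-car files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CRVTable,
    DockingScoreTable,
    Edge,
    ExpressionMatrix,
    InteractionMatrix,
    RunConfig,
    canonical_edge,
)

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"


def read_expression(path, condition: str = "normal", cancer_id: str = "") -> ExpressionMatrix:
    """Read a proteins x samples TSV with protein ids in the first column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file is not a valid expression matrix")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate protein ids {dupes}")
    values = np.empty(df.shape)
    for i, (pid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {pid!r} "
                    f"(line {i + 2}), column {df.columns[j]!r}"
                ) from None
    return ExpressionMatrix(
        protein_ids=tuple(str(p) for p in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=values,
        condition=condition,
        cancer_id=cancer_id,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="protein_id")


def read_edge_list(path) -> frozenset[Edge]:
    """Read a 2-column TSV or SIF edge list into an undirected edge set.

    Duplicate and reversed pairs collapse to one edge; self-loops are
    dropped with a warning.
    """
    path = Path(path)
    edges: set[Edge] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 3 and parts[1] == "pp":
                a, b = parts[0], parts[2]
            elif len(parts) == 2:
                a, b = parts
            else:
                raise ValueError(f"{path}: malformed edge at line {lineno}: {raw!r}")
            if a == b:
                logger.warning("%s: dropping self-loop %r at line %d", path, a, lineno)
                continue
            edges.add(canonical_edge(a, b))
    return frozenset(edges)


def write_edge_list(edges, path, sif: bool = False) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(canonical_edge(x, y) for x, y in edges):
            fh.write(f"{a} pp {b}\n" if sif else f"{a}\t{b}\n")


def read_interaction_matrix(path, condition: str = "normal",
                            cancer_id: str = "") -> InteractionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column protein ids differ")
    return InteractionMatrix(protein_ids=tuple(str(p) for p in df.index),
                             A=df.to_numpy(dtype=float),
                             condition=condition, cancer_id=cancer_id)


def write_interaction_matrix(mat: InteractionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="protein_id")


def read_crv_table(path, n_permutations: int, alpha: float, seed: int,
                   cancer_id: str = "") -> CRVTable:
    df = pd.read_csv(path, sep="\t")
    return CRVTable(protein_ids=tuple(df["protein_id"].astype(str)),
                    crv=df["crv"].to_numpy(dtype=float),
                    pvalue=df["pvalue"].to_numpy(dtype=float),
                    n_permutations=n_permutations, alpha=alpha, seed=seed,
                    cancer_id=cancer_id)


def write_crv_table(table: CRVTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_docking_scores(path) -> DockingScoreTable:
    frame = pd.read_csv(path, dtype={"drug_id": str, "protein_id": str})
    return DockingScoreTable(frame=frame)


def write_docking_scores(table: DockingScoreTable, path) -> None:
    table.frame.to_csv(path, index=False)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps({
        "seed": config.seed, "alpha_crv": config.alpha_crv,
        "alpha_t": config.alpha_t, "n_permutations": config.n_permutations,
        "top_k": config.top_k, "min_targets": config.min_targets,
        "paths": dict(sorted(config.paths.items())),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_metadata(config: RunConfig, path, extra: dict | None = None) -> None:
    """JSON side-car carrying (seed, config hash, tool version) per artifact."""
    meta = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "tool_version": TOOL_VERSION,
        "alpha_crv": config.alpha_crv,
        "alpha_t": config.alpha_t,
        "n_permutations": config.n_permutations,
        "top_k": config.top_k,
        "min_targets": config.min_targets,
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file mirroring its fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"seed", "alpha_crv", "alpha_t", "n_permutations",
               "top_k", "min_targets", "paths"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
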