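"""Published reference tables shipped with the package.

Three small plain-text tables from the four-cancer core-network study:
the 28 core marker proteins, their per-cancer CRVs (bladder, liver,
colorectal, lung), and the docking shortlist of NCI ligands hitting two or
more core proteins.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .types import CRVTable, DockingScoreTable

CANCERS = ("bladder", "liver", "colorectal", "lung")


def _data(name: str):
    return resources.files("coremark").joinpath("data", name)


def core_protein_ids() -> tuple[str, ...]:
    """The 28 core network marker proteins, in published order."""
    with _data("core_proteins.txt").open() as fh:
        return tuple(line.strip() for line in fh
                     if line.strip() and not line.startswith("#"))


def core_crv_frame() -> pd.DataFrame:
    """Per-cancer CRVs of the 28 core proteins (columns per CANCERS)."""
    with _data("core_crv.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def core_crv_tables(alpha: float = 0.01) -> dict[str, CRVTable]:
    """The published CRVs as one CRVTable per cancer.

    The study reports no per-protein p-values for these 28 proteins beyond
    their significance in all four cancers, so p-values are set to alpha
    (exactly at threshold: significant).
    """
    df = core_crv_frame()
    ids = tuple(df["protein_id"])
    tables = {}
    for k in CANCERS:
        tables[k] = CRVTable(
            protein_ids=ids,
            crv=df[k].to_numpy(dtype=float),
            pvalue=np.full(len(ids), alpha),
            n_permutations=100_000,
            alpha=alpha,
            seed=0,
            cancer_id=k,
        )
    return tables


def multi_target_table() -> DockingScoreTable:
    """Published (drug, protein, LibDock score) rows of multi-target ligands."""
    with _data("multi_target_ligands.csv").open() as fh:
        frame = pd.read_csv(fh, dtype={"drug_id": str, "protein_id": str})
    return DockingScoreTable(frame=frame)
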