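"""Clonotype calling and per-sample clonal structure.

A clonotype is the set of cells sharing identical TCR identity under a
chosen key.  Four key modes are supported:

``gene``
    V/J/C segment calls of both chains, ``TRAV_TRAJ_TRAC|TRBV_TRBJ_TRBC``.
``nt``
    concatenated nucleotide CDR3 of both chains (TRA first).
``aa``
    concatenated amino-acid CDR3 of both chains.
``strict``
    gene key plus nucleotide CDR3 key — the default, since cells agreeing
    on segments *and* junction nucleotides are clonal with near certainty.

Clone-size bins follow the Single / Small / Medium / Large / Hyperexpanded
convention with edges 1, 2-5, 6-20, 21-100, >100 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

MODES = ("gene", "nt", "aa", "strict")

SIZE_BINS = [
    ("Single", 1, 1),
    ("Small", 2, 5),
    ("Medium", 6, 20),
    ("Large", 21, 100),
    ("Hyperexpanded", 101, np.inf),
]


@dataclass
class ClonotypeTable:
    """Per-sample clone-size table.

    ``counts`` maps clone key -> cell count n_i; ``N`` is the sample total
    and ``proportions`` the clonal proportions p_i = n_i / N.
    """

    patient: str
    condition: str
    mode: str
    counts: pd.Series

    @property
    def sample(self) -> tuple[str, str]:
        return (self.patient, self.condition)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.counts)

    @property
    def proportions(self) -> pd.Series:
        return self.counts / self.N

    def __post_init__(self) -> None:
        if (self.counts < 1).any():
            raise ValueError("clone counts must be >= 1")
        self.counts = self.counts.astype(int)


def clone_key(cells: pd.DataFrame, mode: str) -> pd.Series:
    """Clone key per cell row, chain-order normalized (TRA first)."""
    if mode not in MODES:
        raise ValueError(f"unknown clone-key mode {mode!r}")
    gene = (cells["tra_v"] + "_" + cells["tra_j"] + "_" + cells["tra_c"]
            + "|" + cells["trb_v"] + "_" + cells["trb_j"] + "_" + cells["trb_c"])
    nt = cells["tra_cdr3_nt"] + "|" + cells["trb_cdr3_nt"]
    if mode == "gene":
        return gene
    if mode == "nt":
        return nt
    if mode == "aa":
        return cells["tra_cdr3_aa"] + "|" + cells["trb_cdr3_aa"]
    return gene + ";" + nt


def call_clonotypes(cells: pd.DataFrame, mode: str = "strict",
                    subset: str | None = None) -> dict[tuple[str, str], ClonotypeTable]:
    """Aggregate cells into per-sample clonotype tables.

    ``cells`` is a metadata-joined paired-cell frame (patient, condition,
    subset columns present).  ``subset`` optionally restricts to one T-cell
    subset (e.g. ``"CD8"``) before counting; proportions are renormalized
    within the restriction.
    """
    if subset is not None:
        cells = cells[cells["subset"] == subset]
    tables: dict[tuple[str, str], ClonotypeTable] = {}
    if cells.empty:
        return tables
    keyed = cells.assign(_key=clone_key(cells, mode))
    for (pt, cond), grp in keyed.groupby(["patient", "condition"], sort=True):
        counts = grp["_key"].value_counts().sort_index()
        tables[(pt, cond)] = ClonotypeTable(pt, cond, mode, counts)
    return tables


def bin_clone_sizes(table: ClonotypeTable) -> pd.DataFrame:
    """Clone counts and occupied repertoire space per size bin.

    ``cell_fraction`` is the fraction of cells carried by clones in each
    bin (the "occupied repertoire space").
    """
    sizes = table.counts.to_numpy()
    rows = []
    for label, lo, hi in SIZE_BINS:
        mask = (sizes >= lo) & (sizes <= hi)
        rows.append({
            "bin": label,
            "min_size": lo,
            "max_size": hi,
            "clone_count": int(mask.sum()),
            "cell_fraction": float(sizes[mask].sum() / table.N),
        })
    return pd.DataFrame(rows)


def unique_clone_fraction(table: ClonotypeTable, denominator: str = "clonotypes") -> float:
    """Fraction of singleton clonotypes.

    ``denominator="clonotypes"`` (default): singletons / clonotypes.
    ``denominator="cells"``: singleton cells / total cells.
    """
    singletons = int((table.counts == 1).sum())
    if denominator == "clonotypes":
        return singletons / table.n_clonotypes
    if denominator == "cells":
        return singletons / table.N
    raise ValueError("denominator must be 'clonotypes' or 'cells'")


def cdr3_length_distribution(cells: pd.DataFrame, chain: str = "both"
                             ) -> dict[tuple[str, str], pd.Series]:
    """Per-sample histogram of amino-acid CDR3 lengths.

    ``chain="both"`` pools the TRA and TRB per-chain length observations
    (two observations per cell), not per-cell sums.
    """
    cols = {"TRA": ["tra_cdr3_aa"], "TRB": ["trb_cdr3_aa"],
            "both": ["tra_cdr3_aa", "trb_cdr3_aa"]}[chain]
    out: dict[tuple[str, str], pd.Series] = {}
    for (pt, cond), grp in cells.groupby(["patient", "condition"], sort=True):
        lengths = pd.concat([grp[c].str.len() for c in cols])
        out[(pt, cond)] = lengths.value_counts().sort_index()
    return out


def top_clones_flow(pre: ClonotypeTable, post: ClonotypeTable, n: int = 10) -> pd.DataFrame:
    """Pre/post frequency flow over the union of each sample's top-n clones.

    Status is ``persisting`` (present in both), ``lost`` (pre only) or
    ``novel`` (post only).
    """
    if pre.patient != post.patient:
        raise ValueError(f"patient mismatch: {pre.patient} vs {post.patient}")
    if pre.mode != post.mode:
        raise ValueError("clone-key mode mismatch")
    top = pre.counts.nlargest(n).index.union(post.counts.nlargest(n).index)
    p_pre = pre.proportions.reindex(top, fill_value=0.0)
    p_post = post.proportions.reindex(top, fill_value=0.0)
    status = np.where(p_pre > 0, np.where(p_post > 0, "persisting", "lost"), "novel")
    return (pd.DataFrame({"clone": top, "freq_pre": p_pre.values,
                          "freq_post": p_post.values, "status": status})
            .sort_values(["freq_pre", "freq_post"], ascending=False)
            .reset_index(drop=True))


def clonal_scatter(pre: ClonotypeTable, post: ClonotypeTable) -> pd.DataFrame:
    """Per-clone (p_pre, p_post) pairs over the union of clone keys."""
    if pre.patient != post.patient:
        raise ValueError(f"patient mismatch: {pre.patient} vs {post.patient}")
    keys = pre.counts.index.union(post.counts.index)
    return pd.DataFrame({
        "clone": keys,
        "p_pre": pre.proportions.reindex(keys, fill_value=0.0).values,
        "p_post": post.proportions.reindex(keys, fill_value=0.0).values,
    })


def iter_patient_pairs(tables: dict[tuple[str, str], ClonotypeTable],
                       pre: str = "pre_GFD", post: str = "post_GFD"
                       ) -> Iterator[tuple[str, ClonotypeTable, ClonotypeTable]]:
    """Yield (patient, pre_table, post_table) for patients with both conditions."""
    patients = sorted({pt for pt, _ in tables})
    for pt in patients:
        if (pt, pre) in tables and (pt, post) in tables:
            yield pt, tables[(pt, pre)], tables[(pt, post)]
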