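"""Contig-table parsing, chain filtering and metadata joining.

Single-cell V(D)J pipelines emit one row per assembled contig; a cell may
carry zero, one or several candidate chains per locus.  This module reads the
two common table dialects (10x Genomics ``filtered_contig_annotations.csv``
and AIRR Rearrangement TSV), standardizes barcodes with a sample prefix,
reduces each cell to a single alpha/beta chain pair (highest-UMI chain per
locus, both loci required) and joins per-cell metadata (patient, condition,
T-cell subset).

All tabular data is carried in :class:`pandas.DataFrame` objects whose
columns follow the AIRR-flavoured contig schema (:data:`CONTIG_COLUMNS`) and
the paired-cell schema (:data:`CELL_COLUMNS`).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
LOCI = ("TRA", "TRB")

#: canonical contig-table columns used throughout the package
CONTIG_COLUMNS = [
    "barcode",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "cdr3_nt",
    "cdr3_aa",
    "umis",
    "productive",
]

#: paired-cell columns produced by :func:`filter_chains`
CELL_COLUMNS = [
    "cell_id",
    "tra_v", "tra_j", "tra_c", "tra_cdr3_nt", "tra_cdr3_aa", "tra_umis",
    "trb_v", "trb_j", "trb_c", "trb_cdr3_nt", "trb_cdr3_aa", "trb_umis",
]

AIRR_REQUIRED = ["cell_id", "locus", "v_call", "j_call", "junction",
                 "junction_aa", "duplicate_count", "productive"]
TENX_REQUIRED = ["barcode", "chain", "v_gene", "j_gene", "c_gene", "cdr3",
                 "cdr3_nt", "umis", "productive", "is_cell",
                 "high_confidence"]

_ALLELE_RE = re.compile(r"\*\d+$")


class FormatError(ValueError):
    """Input table does not satisfy the declared dialect contract."""


@dataclass
class FilterLog:
    """Bookkeeping of cells/contigs removed at each filtering step."""

    input_rows: int = 0
    nonproductive: int = 0
    non_tr_locus: int = 0
    bad_cdr3_alphabet: int = 0
    input_barcodes: int = 0
    multi_resolved: int = 0
    no_tra: int = 0
    no_trb: int = 0
    cells_out: int = 0
    no_metadata: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _strip_allele(calls: pd.Series) -> pd.Series:
    return calls.fillna("").astype(str).str.replace(_ALLELE_RE, "", regex=True)


def _as_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return (
        s.astype(str).str.strip().str.upper()
        .isin({"TRUE", "T", "YES", "1", "PRODUCTIVE"})
    )


def read_contigs(path: str | Path, fmt: str, log: FilterLog | None = None) -> pd.DataFrame:
    """Read a contig table into the canonical schema.

    Parameters
    ----------
    path
        CSV/TSV file in the dialect named by ``fmt``.
    fmt
        ``"tenx_csv"`` (Cell Ranger ``filtered_contig_annotations.csv``) or
        ``"airr_tsv"`` (AIRR Rearrangement).
    log
        Optional :class:`FilterLog` accumulating row-level rejection counts.

    Returns
    -------
    DataFrame with :data:`CONTIG_COLUMNS`.  Non-productive contigs, loci
    other than TRA/TRB, and rows whose amino-acid CDR3 leaves the 20-letter
    alphabet are dropped (counts logged).  Allele suffixes (``*01``) are
    stripped from V/J/C calls.
    """
    log = log if log is not None else FilterLog()
    path = Path(path)
    if fmt == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        _require(df, AIRR_REQUIRED, path)
        out = pd.DataFrame({
            "barcode": df["cell_id"],
            "locus": df["locus"].str.upper(),
            "v_call": _strip_allele(df["v_call"]),
            "j_call": _strip_allele(df["j_call"]),
            "c_call": _strip_allele(df["c_call"]) if "c_call" in df else "",
            "cdr3_nt": df["junction"],
            "cdr3_aa": df["junction_aa"],
            "umis": pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(0).astype(int),
            "productive": _as_bool(df["productive"]),
        })
    elif fmt == "tenx_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _require(df, TENX_REQUIRED, path)
        keep = _as_bool(df["is_cell"]) & _as_bool(df["high_confidence"])
        df = df[keep]
        out = pd.DataFrame({
            "barcode": df["barcode"],
            "locus": df["chain"].str.upper(),
            "v_call": _strip_allele(df["v_gene"]),
            "j_call": _strip_allele(df["j_gene"]),
            "c_call": _strip_allele(df["c_gene"]),
            "cdr3_nt": df["cdr3_nt"],
            "cdr3_aa": df["cdr3"],
            "umis": pd.to_numeric(df["umis"], errors="coerce").fillna(0).astype(int),
            "productive": _as_bool(df["productive"]),
        })
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tenx_csv' or 'airr_tsv'")

    log.input_rows += len(out)

    productive = out["productive"]
    log.nonproductive += int((~productive).sum())
    out = out[productive]

    is_tr = out["locus"].isin(LOCI)
    log.non_tr_locus += int((~is_tr).sum())
    out = out[is_tr]

    ok_aa = out["cdr3_aa"].map(lambda s: len(s) >= 1 and set(s) <= AA_ALPHABET)
    n_bad = int((~ok_aa).sum())
    if n_bad:
        logger.warning("%s: rejected %d rows with CDR3 outside the amino-acid alphabet", path.name, n_bad)
    log.bad_cdr3_alphabet += n_bad
    out = out[ok_aa]

    return out.reset_index(drop=True)


def _require(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def standardize_barcodes(contigs: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Prefix every barcode with ``sample_id + '_'`` (idempotent)."""
    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    prefix = sample_id + "_"
    bc = contigs["barcode"].astype(str)
    out = contigs.copy()
    out["barcode"] = bc.where(bc.str.startswith(prefix), prefix + bc)
    return out


def filter_chains(contigs: pd.DataFrame, log: FilterLog | None = None) -> pd.DataFrame:
    """Reduce contigs to one TRA + one TRB chain per barcode.

    Per barcode the single highest-UMI productive chain of each locus is
    kept; UMI ties are broken by lexicographically smallest ``cdr3_nt`` (and
    then remaining fields) so the result is independent of input order.
    Barcodes lacking either locus are removed.

    Returns a paired-cell frame with :data:`CELL_COLUMNS`.
    """
    log = log if log is not None else FilterLog()
    if contigs.empty:
        return pd.DataFrame(columns=CELL_COLUMNS)

    log.input_barcodes = contigs["barcode"].nunique()

    # deterministic winner per (barcode, locus): max umis, then lexicographic
    ordered = contigs.sort_values(
        ["barcode", "locus", "umis", "cdr3_nt", "v_call", "j_call", "c_call"],
        ascending=[True, True, False, True, True, True, True],
        kind="mergesort",
    )
    log.multi_resolved = int(ordered.duplicated(["barcode", "locus"]).sum())
    best = ordered.drop_duplicates(["barcode", "locus"], keep="first")

    wide = best.pivot(index="barcode", columns="locus",
                      values=["v_call", "j_call", "c_call", "cdr3_nt", "cdr3_aa", "umis"])
    for locus in LOCI:
        if ("v_call", locus) not in wide.columns:
            for f in ["v_call", "j_call", "c_call", "cdr3_nt", "cdr3_aa", "umis"]:
                wide[(f, locus)] = pd.NA

    has_tra = wide[("v_call", "TRA")].notna()
    has_trb = wide[("v_call", "TRB")].notna()
    log.no_tra = int((~has_tra & has_trb).sum())
    log.no_trb = int((has_tra & ~has_trb).sum())
    wide = wide[has_tra & has_trb]

    cells = pd.DataFrame({
        "cell_id": wide.index,
        "tra_v": wide[("v_call", "TRA")].values,
        "tra_j": wide[("j_call", "TRA")].values,
        "tra_c": wide[("c_call", "TRA")].values,
        "tra_cdr3_nt": wide[("cdr3_nt", "TRA")].values,
        "tra_cdr3_aa": wide[("cdr3_aa", "TRA")].values,
        "tra_umis": wide[("umis", "TRA")].values.astype(int),
        "trb_v": wide[("v_call", "TRB")].values,
        "trb_j": wide[("j_call", "TRB")].values,
        "trb_c": wide[("c_call", "TRB")].values,
        "trb_cdr3_nt": wide[("cdr3_nt", "TRB")].values,
        "trb_cdr3_aa": wide[("cdr3_aa", "TRB")].values,
        "trb_umis": wide[("umis", "TRB")].values.astype(int),
    }).sort_values("cell_id").reset_index(drop=True)
    log.cells_out = len(cells)
    return cells


def attach_metadata(cells: pd.DataFrame, meta: pd.DataFrame,
                    log: FilterLog | None = None) -> pd.DataFrame:
    """Inner-join paired cells with per-cell metadata.

    ``meta`` must carry unique ``cell_id`` plus ``patient``, ``condition``
    and ``subset`` columns.  Cells without metadata are dropped and counted.
    The (patient, condition) pair identifies a sample downstream.
    """
    log = log if log is not None else FilterLog()
    if meta["cell_id"].duplicated().any():
        dupes = meta.loc[meta["cell_id"].duplicated(), "cell_id"].head().tolist()
        raise ValueError(f"duplicate metadata cell_id(s), e.g. {dupes}")
    merged = cells.merge(meta, on="cell_id", how="inner")
    log.no_metadata = len(cells) - len(merged)
    if merged.empty and len(cells):
        logger.warning("no cells matched the metadata table (%d cells dropped)", len(cells))
    return merged


def write_airr(cells: pd.DataFrame, path: str | Path) -> None:
    """Write paired cells back to AIRR Rearrangement TSV (two rows per cell)."""
    rows = []
    for locus, p in (("TRA", "tra"), ("TRB", "trb")):
        rows.append(pd.DataFrame({
            "cell_id": cells["cell_id"],
            "locus": locus,
            "v_call": cells[f"{p}_v"],
            "j_call": cells[f"{p}_j"],
            "c_call": cells[f"{p}_c"],
            "junction": cells[f"{p}_cdr3_nt"],
            "junction_aa": cells[f"{p}_cdr3_aa"],
            "duplicate_count": cells[f"{p}_umis"],
            "productive": "T",
        }))
    out = pd.concat(rows).sort_values(["cell_id", "locus"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a cell-metadata TSV (cell_id, patient, condition, subset[, subcluster])."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(meta, ["cell_id", "patient", "condition", "subset"], Path(path))
    return meta
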