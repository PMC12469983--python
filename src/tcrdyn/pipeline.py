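"""End-to-end orchestration of the paired pre/post repertoire comparison.

``run_pipeline`` drives io -> clonotypes -> diversity/overlap -> features ->
pairing -> network from a single :class:`RunConfig`, writes every result
table under the output directory and returns a manifest (JSON on disk)
recording the config, the seed, filter counts, per-file SHA-256 digests and
an overall hash.  Identical config + seed produces an identical manifest
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clonotypes as ct
from . import diversity as dv
from . import features as ft
from . import io as rio
from . import network as nw
from . import pairing as pr
from .simulate import PRE, POST, SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class InputSample:
    sample_id: str
    path: str
    format: str = "airr_tsv"


@dataclass
class RunConfig:
    """Validated pipeline configuration (serialized into the manifest)."""

    outdir: str = "tcrdyn_out"
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: list[InputSample] = field(default_factory=list)
    metadata: str | None = None
    clone_mode: str = "strict"
    unit: str = "cells"
    cluster_threshold: float = 0.85
    cluster_chain: str = "TRA"
    alpha: float = 0.05
    bootstrap_B: int = 100
    bootstrap_depth: int | str = "min_sample"
    subset: str | None = None
    write_cohort_files: bool = True

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs either a simulate block or input files")
        if self.inputs and self.metadata is None:
            raise ValueError("file inputs require a metadata table")
        if self.clone_mode not in ct.MODES:
            raise ValueError(f"unknown clone mode {self.clone_mode!r}")
        if not 0.0 < self.cluster_threshold <= 1.0:
            raise ValueError("cluster_threshold must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("simulate") is not None:
            sim = dict(raw["simulate"])
            if sim.get("pairing_effects"):
                from .simulate import PairingEffect
                sim["pairing_effects"] = [PairingEffect(**e) for e in sim["pairing_effects"]]
            for key in ("expanded_size_range", "cdr3_length_support"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SimConfig(**sim)
        if raw.get("inputs"):
            raw["inputs"] = [InputSample(**i) for i in raw["inputs"]]
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, outputs: dict[str, str]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    outputs[path.name] = str(path)


def pairing_by_patient_array(cells: pd.DataFrame, unit: str = "cells"
                             ) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Pairing-category x condition counts stratified by patient.

    Rows are observed TRAV|TRBV pair categories, columns the two
    conditions, strata the patients — the arrangement that directly asks
    whether the pairing distribution differs between conditions within
    each patient.
    """
    if unit == "clonotypes":
        keyed = cells.assign(_key=ct.clone_key(cells, "strict"))
        cells = keyed.drop_duplicates(["patient", "condition", "_key"])
    pair = cells["tra_v"] + "|" + cells["trb_v"]
    pairs = sorted(pair.unique())
    conds = sorted(cells["condition"].unique())
    patients = sorted(cells["patient"].unique())
    pi = {p: i for i, p in enumerate(pairs)}
    ci = {c: i for i, c in enumerate(conds)}
    si = {s: i for i, s in enumerate(patients)}
    counts = np.zeros((len(pairs), len(conds), len(patients)), dtype=int)
    grouped = cells.assign(_pair=pair).groupby(["_pair", "condition", "patient"],
                                               sort=False).size()
    for (p, c, s), n in grouped.items():
        counts[pi[p], ci[c], si[s]] = n
    return counts, pairs, conds, patients


def cohort_cells(sim, log: rio.FilterLog | None = None) -> pd.DataFrame:
    """Filtered, metadata-joined paired cells straight from a simulated cohort.

    Runs the same barcode standardization / chain filtering / metadata join
    the file-based path uses, without touching disk.
    """
    log = log if log is not None else rio.FilterLog()
    frames = []
    for sample_id in sorted(sim.contigs):
        contigs = sim.contigs[sample_id].rename(columns={
            "cell_id": "barcode", "junction": "cdr3_nt",
            "junction_aa": "cdr3_aa", "duplicate_count": "umis",
        })
        contigs["productive"] = True
        frames.append(rio.standardize_barcodes(contigs, sample_id))
    contigs = pd.concat(frames, ignore_index=True)
    log.input_rows = len(contigs)
    cells = rio.filter_chains(contigs, log=log)
    return rio.attach_metadata(cells, sim.meta, log=log)


def _load_cells(config: RunConfig, outdir: Path, outputs: dict[str, str],
                log: rio.FilterLog) -> pd.DataFrame:
    if config.simulate is not None:
        sim = simulate_cohort(config.simulate)
        if config.write_cohort_files:
            paths = write_cohort(sim, outdir / "cohort")
            outputs.update({f"cohort/{Path(p).name}": p for p in paths.values()})
        return cohort_cells(sim, log=log)
    frames = []
    for inp in config.inputs:
        recs = rio.read_contigs(inp.path, inp.format, log=log)
        frames.append(rio.standardize_barcodes(recs, inp.sample_id))
    contigs = pd.concat(frames, ignore_index=True)
    meta = rio.read_metadata(config.metadata)
    cells = rio.filter_chains(contigs, log=log)
    return rio.attach_metadata(cells, meta, log=log)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    flog = rio.FilterLog()
    stage = "io"
    try:
        cells = _load_cells(config, outdir, outputs, flog)
        rio.write_airr(cells, outdir / "filtered_cells.airr.tsv")
        outputs["filtered_cells.airr.tsv"] = str(outdir / "filtered_cells.airr.tsv")
        flog.to_json(outdir / "filter_log.json")
        outputs["filter_log.json"] = str(outdir / "filter_log.json")

        stage = "clonotypes"
        tables = ct.call_clonotypes(cells, mode=config.clone_mode, subset=config.subset)
        if not tables:
            raise ValueError("no samples after filtering")
        clono_rows = []
        for (pt, cond), tab in sorted(tables.items()):
            df = tab.counts.rename_axis("clone").rename("n").reset_index()
            df.insert(0, "condition", cond)
            df.insert(0, "patient", pt)
            df["p"] = df["n"] / tab.N
            clono_rows.append(df)
        _write(pd.concat(clono_rows, ignore_index=True),
               outdir / "clonotype_tables.tsv", outputs)

        bins = []
        uniq_rows = []
        for (pt, cond), tab in sorted(tables.items()):
            b = ct.bin_clone_sizes(tab)
            b.insert(0, "condition", cond)
            b.insert(0, "patient", pt)
            bins.append(b)
            uniq_rows.append({
                "patient": pt, "condition": cond,
                "unique_fraction_clonotypes": ct.unique_clone_fraction(tab),
                "unique_fraction_cells": ct.unique_clone_fraction(tab, "cells"),
                "n_clonotypes": tab.n_clonotypes, "N": tab.N,
                "clone_mode": tab.mode,
            })
        _write(pd.concat(bins, ignore_index=True), outdir / "size_bins.tsv", outputs)
        uniq = pd.DataFrame(uniq_rows)
        _write(uniq, outdir / "unique_clone_fraction.tsv", outputs)

        lengths = ct.cdr3_length_distribution(cells, chain="both")
        lrows = []
        for (pt, cond), hist in lengths.items():
            df = hist.rename_axis("length").rename("count").reset_index()
            df.insert(0, "condition", cond)
            df.insert(0, "patient", pt)
            lrows.append(df)
        _write(pd.concat(lrows, ignore_index=True), outdir / "cdr3_lengths.tsv", outputs)

        flows, scatters = [], []
        for pt, pre_t, post_t in ct.iter_patient_pairs(tables):
            f = ct.top_clones_flow(pre_t, post_t)
            f.insert(0, "patient", pt)
            flows.append(f)
            s = ct.clonal_scatter(pre_t, post_t)
            s.insert(0, "patient", pt)
            scatters.append(s)
        if flows:
            _write(pd.concat(flows, ignore_index=True), outdir / "top_clones_flow.tsv", outputs)
            _write(pd.concat(scatters, ignore_index=True), outdir / "clonal_scatter.tsv", outputs)

        stage = "diversity"
        boot = dv.bootstrap_diversity(tables, B=config.bootstrap_B,
                                      depth=config.bootstrap_depth, seed=config.seed)
        drows = []
        for (pt, cond), res in sorted(boot.items()):
            row = {"patient": pt, "condition": cond, "S_obs": res.S_obs,
                   "B": res.B, "depth": res.depth}
            row.update(res.point_estimates())
            row.update({f"boot_mean_{k}": v for k, v in res.boot_mean.items()})
            row.update({f"boot_sd_{k}": v for k, v in res.boot_sd.items()})
            drows.append(row)
        _write(pd.DataFrame(drows), outdir / "diversity.tsv", outputs)

        stage = "overlap"
        if len(tables) >= 2:
            om = dv.overlap_matrix(tables)
            om.values.to_csv(outdir / "overlap_matrix.tsv", sep="\t",
                             float_format="%.10g")
            outputs["overlap_matrix.tsv"] = str(outdir / "overlap_matrix.tsv")
            _write(om.to_long(), outdir / "overlap_long.tsv", outputs)

        stage = "features"
        feat_rows_freq, feat_rows_ent, feat_rows_atch, kmer_rows = [], [], [], []
        keyed = cells.assign(_key=ct.clone_key(cells, config.clone_mode))
        for cond, grp in keyed.groupby("condition", sort=True):
            clones = grp.groupby("_key").agg(
                tra=("tra_cdr3_aa", "first"), trb=("trb_cdr3_aa", "first"),
                tra_nt=("tra_cdr3_nt", "first"), trb_nt=("trb_cdr3_nt", "first"),
                size=("_key", "size")).reset_index()
            for chain, col in (("TRA", "tra"), ("TRB", "trb")):
                pairs = list(zip(clones[col], clones["size"].astype(float)))
                prof = ft.positional_atchley(pairs, chain=chain)
                ft.positional_entropy(prof)
                f = prof.freq.reset_index()
                f.insert(0, "chain", chain)
                f.insert(0, "condition", cond)
                feat_rows_freq.append(f)
                e = prof.entropy.rename("entropy").reset_index()
                e.insert(0, "chain", chain)
                e.insert(0, "condition", cond)
                feat_rows_ent.append(e)
                a = prof.atchley.reset_index()
                a.insert(0, "chain", chain)
                a.insert(0, "condition", cond)
                feat_rows_atch.append(a)
                for alphabet, c in (("aa", col), ("nt", f"{col}_nt")):
                    kt = ft.kmer_percentages(
                        list(zip(clones[c], clones["size"].astype(float))),
                        k=3, alphabet=alphabet)
                    t = kt.top(25)
                    t.insert(0, "alphabet", alphabet)
                    t.insert(0, "chain", chain)
                    t.insert(0, "condition", cond)
                    kmer_rows.append(t)
        _write(pd.concat(feat_rows_freq, ignore_index=True),
               outdir / "positional_aa_freq.tsv", outputs)
        _write(pd.concat(feat_rows_ent, ignore_index=True),
               outdir / "positional_entropy.tsv", outputs)
        _write(pd.concat(feat_rows_atch, ignore_index=True),
               outdir / "positional_atchley.tsv", outputs)
        _write(pd.concat(kmer_rows, ignore_index=True),
               outdir / "kmer_top.tsv", outputs)

        stage = "pairing"
        for seg in ("TRAV", "TRBV", "TRAJ", "TRBJ"):
            gu = pr.gene_usage(cells, seg).reset_index()
            _write(gu, outdir / f"gene_usage_{seg}.tsv", outputs)
        parr = pr.pairing_array(cells, "TRAV", "TRBV", strata="condition",
                                unit=config.unit, subset=config.subset)
        _write(parr.to_long(), outdir / "pairing_counts.tsv", outputs)
        fisher = pr.per_pair_fisher(parr)
        _write(fisher.sort_values("p").reset_index(drop=True),
               outdir / "pairing_fisher.tsv", outputs)

        cmh_out = {}
        by_pat, _, _, _ = pairing_by_patient_array(cells, unit=config.unit)
        res = pr.cmh_general(by_pat, arrangement="pairing x condition | patient")
        cmh_out["pairing_x_condition_by_patient"] = asdict(res)
        res2 = pr.cmh_general(parr.counts, arrangement="TRAV x TRBV | condition")
        cmh_out["trav_x_trbv_by_condition"] = asdict(res2)
        (outdir / "cmh_results.json").write_text(json.dumps(cmh_out, indent=2) + "\n")
        outputs["cmh_results.json"] = str(outdir / "cmh_results.json")

        stage = "network"
        edge_rows, node_rows, comp_rows = [], [], []
        for pt, grp in keyed.groupby("patient", sort=True):
            clones = grp.groupby(["_key", "condition"]).agg(
                tra_cdr3_aa=("tra_cdr3_aa", "first"),
                trb_cdr3_aa=("trb_cdr3_aa", "first"),
                size=("_key", "size")).reset_index()
            graph = nw.cluster_clones(clones, threshold=config.cluster_threshold,
                                      chain=config.cluster_chain, group=pt)
            edges, nodes = nw.export_network(graph)
            edges.insert(0, "patient", pt)
            nodes.insert(0, "patient", pt)
            comp = graph.cluster_composition()
            comp.insert(0, "patient", pt)
            edge_rows.append(edges)
            node_rows.append(nodes)
            comp_rows.append(comp)
        _write(pd.concat(edge_rows, ignore_index=True), outdir / "network_edges.tsv", outputs)
        _write(pd.concat(node_rows, ignore_index=True), outdir / "network_nodes.tsv", outputs)
        _write(pd.concat(comp_rows, ignore_index=True), outdir / "network_clusters.tsv", outputs)

        stage = "report"
        report = compare_conditions(uniq, boot, fisher, alpha=config.alpha)
        _write(report, outdir / "summary_report.tsv", outputs)
    except Exception as err:
        partial = {"status": "error", "stage": stage, "error": str(err),
                   "outputs": outputs}
        (outdir / "manifest.json").write_text(json.dumps(partial, indent=2) + "\n")
        raise

    digests = {name: _sha256(Path(p)) for name, p in sorted(outputs.items())}
    overall = hashlib.sha256(
        json.dumps(digests, sort_keys=True).encode()).hexdigest()
    manifest = {
        "status": "ok",
        "package": "tcrdyn",
        "seed": config.seed,
        "config": config.to_dict(),
        "filter_log": asdict(flog),
        "outputs": digests,
        "manifest_hash": overall,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def compare_conditions(uniq: pd.DataFrame,
                       boot: dict[tuple[str, str], dv.DiversityResult],
                       fisher: pd.DataFrame, alpha: float = 0.05,
                       pre: str = PRE, post: str = POST) -> pd.DataFrame:
    """Cohort-level pre/post summary: one row per metric plus top pairs.

    Values are taken verbatim from the stage outputs (no recomputation):
    per-patient deltas of the unique-clone fraction and of each bootstrap
    diversity mean, with the paired t-test over patients, followed by the
    strongest pairing shifts ranked by |log OR|.
    """
    patients = sorted(uniq["patient"].unique())
    both = [pt for pt in patients
            if {pre, post} <= set(uniq.loc[uniq["patient"] == pt, "condition"])]
    rows = []
    if len(both) < 2:
        rows.append({"metric": "comparability", "detail": "fewer than 2 patients "
                     "with both conditions; paired tests skipped",
                     "value": float(len(both)), "p": np.nan})
        return pd.DataFrame(rows)

    def _paired(metric: str, pre_v: list[float], post_v: list[float]) -> None:
        res = dv.paired_condition_test(np.array(pre_v), np.array(post_v))
        rows.append({"metric": metric, "detail": f"paired t over {len(both)} patients",
                     "value": res.mean_diff, "t": res.t, "p": res.p,
                     "significant": bool(res.p < alpha) if not res.zero_variance else False})

    u = uniq.set_index(["patient", "condition"])
    _paired("unique_clone_fraction_delta",
            [u.loc[(pt, pre), "unique_fraction_clonotypes"] for pt in both],
            [u.loc[(pt, post), "unique_fraction_clonotypes"] for pt in both])
    for name in dv.INDEX_NAMES:
        _paired(f"{name}_boot_mean_delta",
                [boot[(pt, pre)].boot_mean[name] for pt in both],
                [boot[(pt, post)].boot_mean[name] for pt in both])

    top = fisher.reindex(fisher["log_odds_ratio"].abs()
                         .sort_values(ascending=False).index).head(10)
    for _, r in top.iterrows():
        rows.append({"metric": "pairing_shift",
                     "detail": f"{r['gene_a']}|{r['gene_b']} {r['direction']}",
                     "value": r["log_odds_ratio"], "p": r["p"],
                     "significant": bool(r["p_adj"] < alpha)})
    return pd.DataFrame(rows)
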