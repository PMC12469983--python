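"""Paired pre/post-intervention TCR repertoire simulator with ground truth.

Emulates a longitudinal design in which patients are sampled before and
after an intervention (here labelled pre_GFD / post_GFD after the
gluten-free-diet study design): a minority of pre-intervention clones are
clonally expanded, expanded clones contract after the intervention, part of
the repertoire turns over into novel singletons, and specific TRAV-TRBV
chain pairings are enriched in one condition while marginal gene usage
stays put.

Every quantity the downstream pipeline estimates (clone sizes, unique-clone
fractions, pairing log-odds) is recorded exactly in a :class:`SimTruth`
object at generation time.

Draw order (a contract — reordering is a breaking change):

1. cohort-level usage vectors, one Dirichlet draw per segment class
   (TRAV, TRAJ, TRBV, TRBJ);
2. per patient, in patient order: four patient-level usage vectors;
3. per patient: pre-condition clone sizes (expanded flags, sizes), gene
   assignments, CDR3 pairs; then post persistence flags and novel-clone
   fill, with gene assignments and CDR3s for the novel clones;
4. per sample, in (patient, condition) order: per-chain UMI counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

PRE, POST = "pre_GFD", "post_GFD"

# modest, realistic default gene pools (IMGT-style names, allele-free)
TRAV_POOL = [
    "TRAV1-1", "TRAV1-2", "TRAV2", "TRAV3", "TRAV4", "TRAV5", "TRAV6",
    "TRAV8-1", "TRAV8-2", "TRAV9-2", "TRAV10", "TRAV12-1", "TRAV12-2",
    "TRAV13-1", "TRAV17", "TRAV19", "TRAV21", "TRAV26-1", "TRAV26-2",
    "TRAV29",
]
TRBV_POOL = [
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-2", "TRBV7-2",
    "TRBV7-9", "TRBV9", "TRBV11-2", "TRBV12-3", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV30",
]
TRAJ_POOL = [
    "TRAJ4", "TRAJ6", "TRAJ9", "TRAJ12", "TRAJ16", "TRAJ20", "TRAJ23",
    "TRAJ27", "TRAJ30", "TRAJ33", "TRAJ37", "TRAJ40", "TRAJ43", "TRAJ45",
    "TRAJ49",
]
TRBJ_POOL = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# standard genetic code, inverted: residue -> synonymous codons
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}


@dataclass
class PairingEffect:
    """Multiplicative log-odds tilt on one TRAV-TRBV pair in one condition."""

    trav: str
    trbv: str
    log_odds: float
    condition: str  # condition in which the tilt applies (PRE or POST)


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the 5-patient paired design."""

    n_patients: int = 5
    cells_per_sample: int | Sequence[int] | None = None  # None: uniform 1500-3500 per patient
    trav_pool: Sequence[str] = field(default_factory=lambda: list(TRAV_POOL))
    trbv_pool: Sequence[str] = field(default_factory=lambda: list(TRBV_POOL))
    traj_pool: Sequence[str] = field(default_factory=lambda: list(TRAJ_POOL))
    trbj_pool: Sequence[str] = field(default_factory=lambda: list(TRBJ_POOL))
    usage_concentration: float = 1.0   # Dirichlet alpha per gene, cohort level
    patient_noise: float = 0.01        # patient alpha = cohort_mean / patient_noise
    expanded_fraction_pre: float = 0.08
    expanded_size_range: tuple[int, int] = (6, 100)
    geometric_p: float = 0.5           # body sizes: truncated geometric on [1,5]
    contraction_factor: float = 0.3
    persistence_prob: float = 0.6
    pairing_effects: Sequence[PairingEffect] = field(default_factory=lambda: [
        PairingEffect("TRAV12-2", "TRBV14", math.log(8.0), POST),
        PairingEffect("TRAV10", "TRBV28", math.log(8.0), POST),
        PairingEffect("TRAV2", "TRBV6-2", math.log(8.0), PRE),
        PairingEffect("TRAV26-2", "TRBV7-2", math.log(8.0), PRE),
    ])
    cdr3_length_support: tuple[int, int] = (8, 20)
    cdr3_length_mode: int = 14
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for p in (self.expanded_fraction_pre, self.persistence_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.contraction_factor <= 1.0:
            raise ValueError("contraction_factor must lie in (0, 1]")
        lo, hi = self.expanded_size_range
        if not (2 <= lo <= hi <= 100):
            raise ValueError("expanded_size_range must lie within [2, 100]")
        for pool in (self.trav_pool, self.trbv_pool, self.traj_pool, self.trbj_pool):
            if not pool:
                raise ValueError("gene pools must be non-empty")
        counts = self.resolve_cell_counts()
        if hi > min(counts):
            raise ValueError(
                f"expanded_size_range max {hi} exceeds smallest sample size {min(counts)}")
        for eff in self.pairing_effects:
            if eff.trav not in self.trav_pool or eff.trbv not in self.trbv_pool:
                raise ValueError(f"pairing effect {eff.trav}-{eff.trbv} outside gene pools")
            if eff.condition not in (PRE, POST):
                raise ValueError(f"pairing effect condition must be {PRE} or {POST}")

    def resolve_cell_counts(self) -> list[int]:
        """Per-patient cells per sample (same target for both conditions)."""
        if self.cells_per_sample is None:
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 915]))
            return [int(x) for x in rng.integers(1500, 3501, size=self.n_patients)]
        if isinstance(self.cells_per_sample, (int, np.integer)):
            return [int(self.cells_per_sample)] * self.n_patients
        counts = [int(x) for x in self.cells_per_sample]
        if len(counts) != self.n_patients:
            raise ValueError("cells_per_sample list length must equal n_patients")
        return counts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "pairing_effects" in raw and raw["pairing_effects"] is not None:
            raw["pairing_effects"] = [PairingEffect(**e) for e in raw["pairing_effects"]]
        for key in ("expanded_size_range", "cdr3_length_support"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pairing_effects"] = [{**asdict(e), "log_odds": float(e.log_odds)}
                                for e in self.pairing_effects]
        d["expanded_size_range"] = list(self.expanded_size_range)
        d["cdr3_length_support"] = list(self.cdr3_length_support)
        if d["cells_per_sample"] is not None and not isinstance(d["cells_per_sample"], int):
            d["cells_per_sample"] = list(d["cells_per_sample"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SimTruth:
    """Exact generation-time record of what the cohort contains."""

    clones: pd.DataFrame        # patient, condition, clone_id, genes, CDR3s, size, expanded, fate, subset
    pair_effects: pd.DataFrame  # trav, trbv, log_odds, condition
    unique_fraction: pd.DataFrame  # patient, condition, n_clones, n_singletons, unique_fraction

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clones": self.clones.to_dict(orient="list"),
            "pair_effects": self.pair_effects.to_dict(orient="list"),
            "unique_fraction": self.unique_fraction.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


@dataclass
class SimResult:
    contigs: dict[str, pd.DataFrame]  # sample_id -> AIRR-style contig table
    meta: pd.DataFrame                # cell_id, patient, condition, subset
    truth: SimTruth


def _random_seqs(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """CDR3 amino-acid strings: 'C' + uniform interior + 'F'."""
    inner = lengths - 2
    total = int(inner.sum())
    flat = AA20[rng.integers(0, 20, size=total)]
    out, pos = [], 0
    for n in inner:
        out.append("C" + "".join(flat[pos:pos + n]) + "F")
        pos += n
    return out


_AA_INDEX = {a: i for i, a in enumerate(AA20)}
_N_CODONS = np.array([len(_CODONS[a]) for a in AA20])
_CODON_ARR = np.array([(_CODONS[a] + [""] * 6)[:6] for a in AA20])


def _back_translate(rng: np.random.Generator, seqs: list[str]) -> list[str]:
    """Uniform synonymous-codon back-translation (vectorized over residues)."""
    cat = "".join(seqs)
    if not cat:
        return ["" for _ in seqs]
    idx = np.fromiter((_AA_INDEX[a] for a in cat), dtype=np.int64, count=len(cat))
    pick = rng.integers(0, _N_CODONS[idx])
    codons = _CODON_ARR[idx, pick]
    out, pos = [], 0
    for s in seqs:
        out.append("".join(codons[pos:pos + len(s)]))
        pos += len(s)
    return out


def _length_probs(support: tuple[int, int], mode: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = support
    lengths = np.arange(lo, hi + 1)
    # triangular mass, strictly positive at the endpoints
    left = (lengths - lo + 1) / (mode - lo + 1)
    right = (hi - lengths + 1) / (hi - mode + 1)
    probs = np.minimum(left, right)
    return lengths, probs / probs.sum()


def _pair_matrix(p_trav: np.ndarray, p_trbv: np.ndarray, config: SimConfig,
                 condition: str) -> np.ndarray:
    """Joint TRAV x TRBV probabilities: independence tilted by the effects."""
    joint = np.outer(p_trav, p_trbv)
    for eff in config.pairing_effects:
        if eff.condition == condition:
            i = list(config.trav_pool).index(eff.trav)
            j = list(config.trbv_pool).index(eff.trbv)
            joint[i, j] *= np.exp(eff.log_odds)
    return joint / joint.sum()


def _draw_sizes(rng: np.random.Generator, target: int, config: SimConfig
                ) -> tuple[np.ndarray, np.ndarray]:
    """Clone sizes summing exactly to ``target``; returns (sizes, expanded)."""
    lo, hi = config.expanded_size_range
    geo = config.geometric_p ** np.arange(1, 6)
    geo = geo / geo.sum()
    sizes, expanded = [], []
    total = 0
    while total < target:
        k = max(16, (target - total) // 2)
        exp_flags = rng.random(k) < config.expanded_fraction_pre
        body = rng.choice(np.arange(1, 6), size=k, p=geo)
        big = rng.integers(lo, hi + 1, size=k)
        s = np.where(exp_flags, big, body)
        for sz, fl in zip(s, exp_flags):
            if total >= target:
                break
            sz = int(min(sz, target - total))
            sizes.append(sz)
            expanded.append(bool(fl) and sz >= lo)
            total += sz
    return np.asarray(sizes, dtype=int), np.asarray(expanded, dtype=bool)


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate the paired cohort; identical config+seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7011]))
    counts = config.resolve_cell_counts()
    pools = {
        "trav": np.asarray(config.trav_pool),
        "trbv": np.asarray(config.trbv_pool),
        "traj": np.asarray(config.traj_pool),
        "trbj": np.asarray(config.trbj_pool),
    }

    # 1. cohort usage
    cohort = {k: rng.dirichlet(np.full(len(v), config.usage_concentration))
              for k, v in pools.items()}
    # 2. patient usage
    patients = [f"CEL_{i + 1:02d}" for i in range(config.n_patients)]
    patient_usage = {
        pt: {k: rng.dirichlet(cohort[k] / config.patient_noise) for k in pools}
        for pt in patients
    }

    lengths_sup, length_p = _length_probs(config.cdr3_length_support, config.cdr3_length_mode)

    clone_rows: list[pd.DataFrame] = []
    for pt, target in zip(patients, counts):
        u = patient_usage[pt]
        pair_pre = _pair_matrix(u["trav"], u["trbv"], config, PRE)
        pair_post = _pair_matrix(u["trav"], u["trbv"], config, POST)

        # 3a. pre clones
        sizes, expanded = _draw_sizes(rng, target, config)
        n = len(sizes)
        flat = rng.choice(pair_pre.size, size=n, p=pair_pre.ravel())
        iv, jv = np.unravel_index(flat, pair_pre.shape)
        traj = rng.choice(len(pools["traj"]), size=n, p=u["traj"])
        trbj = rng.choice(len(pools["trbj"]), size=n, p=u["trbj"])
        lens_a = rng.choice(lengths_sup, size=n, p=length_p)
        lens_b = rng.choice(lengths_sup, size=n, p=length_p)
        aa_a = _random_seqs(rng, lens_a)
        aa_b = _random_seqs(rng, lens_b)
        nt_a = _back_translate(rng, aa_a)
        nt_b = _back_translate(rng, aa_b)
        # expanded clones are mostly cytotoxic CD8; body roughly 58/37/5
        subset = np.where(
            expanded,
            np.where(rng.random(n) < 0.8, "CD8", "CD4"),
            rng.choice(np.array(["CD4", "CD8", "Treg"]), size=n, p=[0.58, 0.37, 0.05]),
        )
        pre = pd.DataFrame({
            "patient": pt, "condition": PRE,
            "clone_id": [f"{pt}_pre{c:05d}" for c in range(n)],
            "trav": pools["trav"][iv], "traj": pools["traj"][traj],
            "trbv": pools["trbv"][jv], "trbj": pools["trbj"][trbj],
            "tra_cdr3_aa": aa_a, "trb_cdr3_aa": aa_b,
            "tra_cdr3_nt": nt_a, "trb_cdr3_nt": nt_b,
            "size": sizes, "expanded": expanded, "fate": "baseline",
            "subset": subset,
        })
        clone_rows.append(pre)

        # 3b. post: persistence + contraction of the expanded tail
        persist = rng.random(n) < config.persistence_prob
        post_sizes = np.where(
            expanded,
            np.maximum(1, np.round(sizes * config.contraction_factor).astype(int)),
            sizes,
        )
        surv = pre[persist].copy()
        surv["size"] = post_sizes[persist]
        # deterministic trim if persistence overshoots the target
        while len(surv) and surv["size"].sum() > target:
            excess = surv["size"].sum() - target
            last = surv.index[-1]
            if surv.at[last, "size"] <= excess:
                surv = surv.iloc[:-1]
            else:
                surv.at[last, "size"] -= excess
        surv["condition"] = POST
        surv["fate"] = "persisted"
        n_fill = target - int(surv["size"].sum())

        flat = rng.choice(pair_post.size, size=n_fill, p=pair_post.ravel())
        iv, jv = np.unravel_index(flat, pair_post.shape)
        traj = rng.choice(len(pools["traj"]), size=n_fill, p=u["traj"])
        trbj = rng.choice(len(pools["trbj"]), size=n_fill, p=u["trbj"])
        lens_a = rng.choice(lengths_sup, size=n_fill, p=length_p)
        lens_b = rng.choice(lengths_sup, size=n_fill, p=length_p)
        aa_a = _random_seqs(rng, lens_a)
        aa_b = _random_seqs(rng, lens_b)
        nt_a = _back_translate(rng, aa_a)
        nt_b = _back_translate(rng, aa_b)
        novel = pd.DataFrame({
            "patient": pt, "condition": POST,
            "clone_id": [f"{pt}_post{c:05d}" for c in range(n_fill)],
            "trav": pools["trav"][iv], "traj": pools["traj"][traj],
            "trbv": pools["trbv"][jv], "trbj": pools["trbj"][trbj],
            "tra_cdr3_aa": aa_a, "trb_cdr3_aa": aa_b,
            "tra_cdr3_nt": nt_a, "trb_cdr3_nt": nt_b,
            "size": 1, "expanded": False, "fate": "novel",
            "subset": rng.choice(np.array(["CD4", "CD8", "Treg"]), size=n_fill,
                                 p=[0.58, 0.37, 0.05]),
        })
        clone_rows.append(pd.concat([surv, novel], ignore_index=True))

    clones = pd.concat(clone_rows, ignore_index=True)

    # 4. emit contig tables + metadata
    contigs: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for pt in patients:
        for cond in (PRE, POST):
            sample_id = f"{pt}_{cond}"
            sub = clones[(clones["patient"] == pt) & (clones["condition"] == cond)]
            reps = sub["size"].to_numpy()
            n_cells = int(reps.sum())
            barcodes = np.array([f"BC{i:05d}-1" for i in range(n_cells)])
            umis_a = 1 + rng.poisson(3.0, size=n_cells)
            umis_b = 1 + rng.poisson(3.0, size=n_cells)

            def _rep(col: str) -> np.ndarray:
                return np.repeat(sub[col].to_numpy(), reps)

            tra = pd.DataFrame({
                "cell_id": barcodes, "locus": "TRA",
                "v_call": _rep("trav"), "j_call": _rep("traj"), "c_call": "TRAC",
                "junction": _rep("tra_cdr3_nt"), "junction_aa": _rep("tra_cdr3_aa"),
                "duplicate_count": umis_a, "productive": "T",
            })
            trb = pd.DataFrame({
                "cell_id": barcodes, "locus": "TRB",
                "v_call": _rep("trbv"), "j_call": _rep("trbj"), "c_call": "TRBC2",
                "junction": _rep("trb_cdr3_nt"), "junction_aa": _rep("trb_cdr3_aa"),
                "duplicate_count": umis_b, "productive": "T",
            })
            contigs[sample_id] = pd.concat([tra, trb], ignore_index=True)
            meta_rows.append(pd.DataFrame({
                "cell_id": sample_id + "_" + barcodes,
                "patient": pt, "condition": cond, "subset": _rep("subset"),
            }))
    meta = pd.concat(meta_rows, ignore_index=True)

    uniq = (
        clones.groupby(["patient", "condition"])
        .agg(n_clones=("size", "size"), n_singletons=("size", lambda s: int((s == 1).sum())))
        .reset_index()
    )
    uniq["unique_fraction"] = uniq["n_singletons"] / uniq["n_clones"]

    effects = pd.DataFrame(
        [(e.trav, e.trbv, e.log_odds, e.condition) for e in config.pairing_effects],
        columns=["trav", "trbv", "log_odds", "condition"],
    )
    return SimResult(contigs=contigs, meta=meta,
                     truth=SimTruth(clones=clones, pair_effects=effects,
                                    unique_fraction=uniq))


def ground_truth_report(truth: SimTruth) -> pd.DataFrame:
    """Long-form truth summary: one row per injected effect and per contrast."""
    rows = []
    for _, e in truth.pair_effects.iterrows():
        rows.append({
            "kind": "pairing_effect",
            "label": f"{e.trav}|{e.trbv}",
            "condition": e.condition,
            "value": float(e.log_odds),
        })
    wide = truth.unique_fraction.pivot(index="patient", columns="condition",
                                       values="unique_fraction")
    for pt, row in wide.iterrows():
        rows.append({
            "kind": "unique_fraction_delta",
            "label": pt,
            "condition": "post_minus_pre",
            "value": float(row[POST] - row[PRE]),
        })
    return pd.DataFrame(rows, columns=["kind", "label", "condition", "value"])


def write_cohort(result: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write AIRR TSVs, metadata TSV and truth JSON; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sample_id, table in result.contigs.items():
        p = outdir / f"{sample_id}.airr.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[sample_id] = str(p)
    meta_path = outdir / "cell_metadata.tsv"
    result.meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = str(meta_path)
    truth_path = outdir / "sim_truth.json"
    result.truth.to_json(truth_path)
    paths["truth"] = str(truth_path)
    return paths
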