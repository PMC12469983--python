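"""CDR3 sequence profiling: positional composition, entropy, Atchley factors, k-mers.

Sequences are left-aligned: position 1 is the first CDR3 residue.  At each
position the denominator is the total weight of sequences long enough to
reach it, so every covered position carries a proper distribution over the
20 amino acids.  Weights default to clone cell counts (repertoire-level
composition); pass weight 1 per clonotype for unique-clonotype profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")
_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}


def atchley_factors() -> pd.DataFrame:
    """The published five-factor amino-acid table (20 x 5), index = residue."""
    with resources.files("tcrdyn.data").joinpath("atchley_factors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="aa")
    return df


@dataclass
class PositionalProfile:
    chain: str
    L_max: int
    freq: pd.DataFrame       # positions x 20 relative frequencies
    coverage: pd.Series      # per-position contributing weight
    entropy: pd.Series | None = None   # per-position, normalized to [0, 1]
    atchley: pd.DataFrame | None = None  # positions x 5 weighted means


def _weighted_counts(cdr3s: list[tuple[str, float]]) -> tuple[np.ndarray, np.ndarray, int]:
    """Position x residue weight matrix; invalid-alphabet rows rejected."""
    valid = []
    rejected = 0
    for seq, w in cdr3s:
        if seq and set(seq) <= set(AA_ORDER):
            valid.append((seq, float(w)))
        else:
            rejected += 1
    if rejected:
        logger.warning("rejected %d CDR3 sequence(s) outside the amino-acid alphabet",
                       rejected)
    if not valid:
        return np.zeros((0, 20)), np.zeros(0), rejected
    l_max = max(len(s) for s, _ in valid)
    counts = np.zeros((l_max, 20))
    for seq, w in valid:
        idx = [_AA_IDX[a] for a in seq]
        counts[np.arange(len(seq)), idx] += w
    return counts, counts.sum(axis=1), rejected


def positional_aa_frequency(cdr3s: list[tuple[str, float]], chain: str = "TRA"
                            ) -> PositionalProfile:
    """Relative amino-acid frequencies per left-aligned CDR3 position."""
    counts, coverage, _ = _weighted_counts(cdr3s)
    l_max = counts.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(coverage[:, None] > 0, counts / coverage[:, None], 0.0)
    positions = pd.RangeIndex(1, l_max + 1, name="position")
    return PositionalProfile(
        chain=chain, L_max=l_max,
        freq=pd.DataFrame(freq, index=positions, columns=AA_ORDER),
        coverage=pd.Series(coverage, index=positions, name="coverage"),
    )


def positional_entropy(profile: PositionalProfile) -> pd.Series:
    """Per-position Shannon entropy normalized by ln 20 (in [0, 1]).

    Positions with zero coverage are omitted.  The result is also stored on
    the profile.
    """
    f = profile.freq.to_numpy()
    covered = profile.coverage.to_numpy() > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    ent = -plogp.sum(axis=1) / np.log(20.0)
    out = pd.Series(ent, index=profile.freq.index, name="entropy")[covered]
    profile.entropy = out
    return out


def positional_atchley(cdr3s: list[tuple[str, float]], chain: str = "TRA"
                       ) -> PositionalProfile:
    """Weighted mean of each Atchley factor per CDR3 position."""
    profile = positional_aa_frequency(cdr3s, chain=chain)
    table = atchley_factors().loc[AA_ORDER].to_numpy()  # 20 x 5
    means = profile.freq.to_numpy() @ table
    profile.atchley = pd.DataFrame(means, index=profile.freq.index,
                                   columns=list(atchley_factors().columns))
    return profile


@dataclass
class KmerTable:
    alphabet: str  # "nt" or "aa"
    k: int
    counts: pd.Series   # k-mer -> weighted count
    percent: pd.Series  # 100 * count / total

    def top(self, n: int = 25) -> pd.DataFrame:
        top = self.percent.nlargest(n)
        return pd.DataFrame({"kmer": top.index, "percent": top.values,
                             "count": self.counts.reindex(top.index).values})


def kmer_percentages(seqs: list[tuple[str, float]], k: int = 3,
                     alphabet: str = "aa") -> KmerTable:
    """Sliding-window k-mer spectrum, weighted by clone size.

    Sequences shorter than ``k`` contribute nothing; percentages are
    normalized within the sample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, float] = {}
    for seq, w in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0.0) + w
    series = pd.Series(counts, dtype=float).sort_index()
    total = float(series.sum()) if len(series) else 0.0
    percent = 100.0 * series / total if total > 0 else series.copy()
    return KmerTable(alphabet=alphabet, k=k, counts=series, percent=percent)
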