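"""Clonal diversity indices, bootstrap downsampling, paired tests, overlap.

Six indices summarize each repertoire's richness and evenness:

- Shannon entropy ``H = -sum p_i ln p_i`` (nats),
- inverse Simpson ``1 / sum p_i^2``,
- Gini-Simpson ``1 - sum p_i^2``,
- normalized entropy ``H / ln S_obs`` (defined 0 for a single clone),
- Chao1 (bias-corrected): ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``,
- ACE, the abundance-based coverage estimator with rare cutoff 10.

Because richer samples mechanically score higher, cross-sample comparison
uses bootstrap resampling of cells at a common downsampling depth.

Repertoire overlap is the Morisita–Horn index on clonal proportions, which
is bounded in [0, 1] (0 disjoint, 1 identical composition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clonotypes import ClonotypeTable

INDEX_NAMES = ("shannon", "inv_simpson", "gini_simpson", "norm_entropy", "chao1", "ace")

ACE_CUTOFF = 10


@dataclass
class DiversityResult:
    patient: str
    condition: str
    S_obs: int
    shannon: float
    inv_simpson: float
    gini_simpson: float
    norm_entropy: float
    chao1: float
    ace: float
    f_k: dict[int, int]
    C_ACE: float
    gamma_sq: float
    boot_mean: dict[str, float] = field(default_factory=dict)
    boot_sd: dict[str, float] = field(default_factory=dict)
    B: int = 0
    depth: int = 0

    def point_estimates(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _indices_from_counts(counts: np.ndarray, chao1_bias_corrected: bool = True
                         ) -> dict[str, float]:
    """All six indices from a vector of clone sizes (direct formulas)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty repertoire")
    p = counts / n
    s_obs = len(counts)
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p ** 2).sum())
    inv_simpson = 1.0 / sum_p2
    gini_simpson = 1.0 - sum_p2
    norm_entropy = shannon / math.log(s_obs) if s_obs > 1 else 0.0

    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if chao1_bias_corrected:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s_obs + (f1 * f1 / (2.0 * f2) if f2 > 0 else 0.0)

    rare = counts[counts <= ACE_CUTOFF]
    s_rare = len(rare)
    s_abund = s_obs - s_rare
    n_rare = rare.sum()
    c_ace = 1.0 - f1 / n_rare if n_rare > 0 else 0.0
    if c_ace <= 0.0 or n_rare <= 1:
        ace = chao1
        gamma_sq = 0.0
    else:
        ks = np.arange(1, ACE_CUTOFF + 1)
        f_ks = np.array([(counts == k).sum() for k in ks])
        gamma_sq = max(
            s_rare * float((ks * (ks - 1) * f_ks).sum())
            / (c_ace * n_rare * (n_rare - 1)) - 1.0,
            0.0,
        )
        ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq
    return {
        "shannon": shannon, "inv_simpson": inv_simpson,
        "gini_simpson": gini_simpson, "norm_entropy": norm_entropy,
        "chao1": float(chao1), "ace": float(ace),
        "_f1": f1, "_f2": f2, "_C_ACE": float(c_ace), "_gamma_sq": float(gamma_sq),
    }


def diversity_profile(table: ClonotypeTable, chao1_bias_corrected: bool = True
                      ) -> DiversityResult:
    """Point estimates of the six diversity indices for one sample."""
    if table.N < 1:
        raise ValueError("empty clonotype table")
    counts = table.counts.to_numpy()
    vals = _indices_from_counts(counts, chao1_bias_corrected)
    f_k = {k: int((counts == k).sum()) for k in range(1, ACE_CUTOFF + 1)}
    return DiversityResult(
        patient=table.patient, condition=table.condition,
        S_obs=table.n_clonotypes,
        shannon=vals["shannon"], inv_simpson=vals["inv_simpson"],
        gini_simpson=vals["gini_simpson"], norm_entropy=vals["norm_entropy"],
        chao1=vals["chao1"], ace=vals["ace"],
        f_k=f_k, C_ACE=vals["_C_ACE"], gamma_sq=vals["_gamma_sq"],
    )


def bootstrap_diversity(tables: dict[tuple[str, str], ClonotypeTable],
                        B: int = 100, depth: int | str = "min_sample",
                        seed: int = 0) -> dict[tuple[str, str], DiversityResult]:
    """Bootstrap the indices at a common downsampling depth.

    Per replicate, ``depth`` cells are drawn with replacement from the
    cell-level multiset of each sample and all indices recomputed; the
    report carries mean and sd over ``B`` replicates alongside the point
    estimates.  ``depth="min_sample"`` uses the smallest sample's N.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if not tables:
        return {}
    if depth == "min_sample":
        depth_n = min(t.N for t in tables.values())
    else:
        depth_n = int(depth)
        if depth_n > min(t.N for t in tables.values()):
            raise ValueError("fixed depth exceeds the smallest sample")
    if depth_n < 1:
        raise ValueError("depth must be >= 1")

    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], DiversityResult] = {}
    for key in sorted(tables):
        table = tables[key]
        result = diversity_profile(table)
        cells = np.repeat(np.arange(table.n_clonotypes), table.counts.to_numpy())
        reps = {name: np.empty(B) for name in INDEX_NAMES}
        for b in range(B):
            draw = rng.choice(cells, size=depth_n, replace=True)
            sizes = np.bincount(draw, minlength=table.n_clonotypes)
            vals = _indices_from_counts(sizes[sizes > 0])
            for name in INDEX_NAMES:
                reps[name][b] = vals[name]
        result.boot_mean = {k: float(v.mean()) for k, v in reps.items()}
        result.boot_sd = {k: float(v.std(ddof=1)) for k, v in reps.items()}
        result.B = B
        result.depth = depth_n
        out[key] = result
    return out


@dataclass
class PairedTestResult:
    t: float
    p: float
    mean_diff: float
    n: int
    zero_variance: bool


def paired_condition_test(values_pre: np.ndarray, values_post: np.ndarray
                          ) -> PairedTestResult:
    """Classical paired t-test on post-minus-pre differences (df = n - 1)."""
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diffs = post - pre
    n = len(diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(t=math.nan, p=math.nan, mean_diff=mean, n=n,
                                zero_variance=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), p=float(p), mean_diff=mean, n=n,
                            zero_variance=False)


def morisita_overlap(a: ClonotypeTable, b: ClonotypeTable) -> float:
    """Morisita–Horn index between two repertoires, clamped to [0, 1].

    ``C = 2 sum x_i y_i / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y)`` over
    the union of clone keys, with X, Y the sample totals.
    """
    if a.mode != b.mode:
        raise ValueError(f"clone-key mode mismatch: {a.mode} vs {b.mode}")
    keys = a.counts.index.union(b.counts.index)
    x = a.counts.reindex(keys, fill_value=0).to_numpy(dtype=float)
    y = b.counts.reindex(keys, fill_value=0).to_numpy(dtype=float)
    X, Y = x.sum(), y.sum()
    num = 2.0 * float((x * y).sum())
    den = (float((x * x).sum()) / X ** 2 + float((y * y).sum()) / Y ** 2) * X * Y
    return float(min(max(num / den, 0.0), 1.0))


@dataclass
class OverlapMatrix:
    samples: list[tuple[str, str]]
    values: pd.DataFrame  # symmetric, diagonal 1

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.samples):
            for j, b in enumerate(self.samples):
                if j > i:
                    rows.append({
                        "sample_a": "_".join(a), "sample_b": "_".join(b),
                        "morisita": self.values.iat[i, j],
                    })
        return pd.DataFrame(rows)


def overlap_matrix(tables: dict[tuple[str, str], ClonotypeTable]) -> OverlapMatrix:
    """All pairwise Morisita–Horn indices; each unordered pair computed once."""
    samples = sorted(tables)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    k = len(samples)
    m = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = morisita_overlap(tables[samples[i]], tables[samples[j]])
    labels = ["_".join(s) for s in samples]
    return OverlapMatrix(samples=samples,
                         values=pd.DataFrame(m, index=labels, columns=labels))
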