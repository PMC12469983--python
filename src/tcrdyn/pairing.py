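"""V/J gene usage and TRAV-TRBV pairing enrichment statistics.

The central question this module answers: do alpha/beta chain pairings
reorganize between conditions even when marginal gene usage stays stable?
Pairing incidences are summarized as dense gene x gene x stratum count
arrays; a global Cochran-Mantel-Haenszel (CMH) test measures association
across strata, and per-pair 2x2 Fisher exact tests with odds ratios and
Benjamini-Hochberg adjustment localize the shifts.

Odds-ratio orientation: the 2x2 table rows are (pair, not pair) and
columns (pre, post), so OR = (a d)/(b c) > 1 means the pair is relatively
more frequent pre-intervention (``depleted_post``), OR < 1 means
``enriched_post``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clonotypes import clone_key

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = {"TRAV": "tra_v", "TRAJ": "tra_j", "TRBV": "trb_v", "TRBJ": "trb_j"}


def gene_usage(cells: pd.DataFrame, segment_class: str,
               pool: list[str] | None = None) -> pd.DataFrame:
    """Per-sample and per-condition gene-usage proportions.

    Rows are genes (dense over the observed union plus ``pool``), columns
    are samples (``patient_condition``) followed by condition aggregates
    computed from pooled counts.
    """
    col = SEGMENT_COLUMNS[segment_class]
    if cells.empty:
        raise ValueError("no cells")
    genes = sorted(set(cells[col]) | set(pool or []))
    out = {}
    for (pt, cond), grp in cells.groupby(["patient", "condition"], sort=True):
        counts = grp[col].value_counts().reindex(genes, fill_value=0)
        out[f"{pt}_{cond}"] = counts / counts.sum()
    for cond, grp in cells.groupby("condition", sort=True):
        counts = grp[col].value_counts().reindex(genes, fill_value=0)
        out[f"all_{cond}"] = counts / counts.sum()
    return pd.DataFrame(out, index=pd.Index(genes, name=segment_class))


@dataclass
class PairingArray:
    row_class: str
    col_class: str
    row_genes: list[str]
    col_genes: list[str]
    strata: list[str]
    counts: np.ndarray  # rows x cols x strata, non-negative ints
    unit: str           # "cells" or "clonotypes"

    def stratum_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for k, stratum in enumerate(self.strata):
            for i, ga in enumerate(self.row_genes):
                for j, gb in enumerate(self.col_genes):
                    c = int(self.counts[i, j, k])
                    if c:
                        rows.append({"gene_a": ga, "gene_b": gb,
                                     "stratum": stratum, "count": c})
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "stratum", "count"])


def pairing_array(cells: pd.DataFrame, row_class: str = "TRAV",
                  col_class: str = "TRBV", strata: str = "condition",
                  unit: str = "cells", subset: str | None = None,
                  row_pool: list[str] | None = None,
                  col_pool: list[str] | None = None) -> PairingArray:
    """Dense gene x gene x stratum pairing counts.

    ``unit="cells"`` counts every cell; ``unit="clonotypes"`` collapses each
    clonotype (strict key, within its sample) to one observation.  Strata
    are conditions (default) or patients.  ``subset`` restricts to one
    T-cell subset before counting.
    """
    if strata not in ("condition", "patient"):
        raise ValueError("strata must be 'condition' or 'patient'")
    if unit not in ("cells", "clonotypes"):
        raise ValueError("unit must be 'cells' or 'clonotypes'")
    if subset is not None:
        cells = cells[cells["subset"] == subset]
    if unit == "clonotypes":
        keyed = cells.assign(_key=clone_key(cells, "strict"))
        cells = keyed.drop_duplicates(["patient", "condition", "_key"])

    rcol, ccol = SEGMENT_COLUMNS[row_class], SEGMENT_COLUMNS[col_class]
    row_genes = sorted(set(cells[rcol]) | set(row_pool or []))
    col_genes = sorted(set(cells[ccol]) | set(col_pool or []))
    strata_vals = sorted(cells[strata].unique())
    ri = {g: i for i, g in enumerate(row_genes)}
    ci = {g: i for i, g in enumerate(col_genes)}
    si = {s: i for i, s in enumerate(strata_vals)}
    counts = np.zeros((len(row_genes), len(col_genes), len(strata_vals)), dtype=int)
    grouped = cells.groupby([rcol, ccol, strata], sort=False).size()
    for (ga, gb, st), c in grouped.items():
        counts[ri[ga], ci[gb], si[st]] = c
    return PairingArray(row_class=row_class, col_class=col_class,
                        row_genes=row_genes, col_genes=col_genes,
                        strata=strata_vals, counts=counts, unit=unit)


@dataclass
class CMHResult:
    statistic: float
    df: int
    p: float
    arrangement: str
    strata_used: int
    strata_skipped: int = 0


def cmh_2x2xk(tables: np.ndarray, correction: bool = False,
              arrangement: str = "2x2xK") -> CMHResult:
    """Cochran-Mantel-Haenszel test for K stratified 2x2 tables.

    ``tables`` has shape (K, 2, 2).  The statistic is
    ``(|sum_k (a_k - E a_k)| - 0.5 [correction])^2 / sum_k Var a_k`` with
    expectation and variance under the stratum-margin hypergeometric;
    p-value from chi-square with 1 df.  Strata with a zero margin carry no
    information and are skipped.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    num = 0.0
    den = 0.0
    used = skipped = 0
    for t in tables:
        a, b = t[0]
        c, d = t[1]
        n = a + b + c + d
        r1, r0 = a + b, c + d
        c1, c0 = a + c, b + d
        if n <= 1 or min(r1, r0, c1, c0) == 0:
            skipped += 1
            continue
        num += a - r1 * c1 / n
        den += r1 * r0 * c1 * c0 / (n * n * (n - 1))
        used += 1
    if used == 0:
        raise ValueError("all strata degenerate")
    if skipped:
        logger.info("cmh_2x2xk: skipped %d degenerate stratum/strata", skipped)
    stat = (abs(num) - (0.5 if correction else 0.0)) ** 2 / den
    p = float(stats.chi2.sf(stat, df=1))
    return CMHResult(statistic=float(stat), df=1, p=p, arrangement=arrangement,
                     strata_used=used, strata_skipped=skipped)


def cmh_general(array: np.ndarray, arrangement: str = "IxJxK") -> CMHResult:
    """Generalized CMH test of general association for I x J x K counts.

    Per stratum the vector of observed minus expected counts over the
    leading (I-1)(J-1) cells is formed, with its covariance under the
    multiple hypergeometric; the statistic is ``Q = G' V^-1 G`` on the
    stratum sums, chi-square with (I-1)(J-1) df.  A pseudo-inverse is used
    when V is singular, reducing df to rank(V).
    """
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 3:
        raise ValueError("array must be I x J x K")
    I, J, K = arr.shape
    if I < 2 or J < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    dim = (I - 1) * (J - 1)
    G = np.zeros(dim)
    V = np.zeros((dim, dim))
    used = skipped = 0
    for k in range(K):
        t = arr[:, :, k]
        N = t.sum()
        if N <= 1:
            skipped += 1
            continue
        r = t.sum(axis=1)
        c = t.sum(axis=0)
        expected = np.outer(r, c) / N
        G += (t - expected)[:-1, :-1].ravel()
        # Cov(n_ij, n_i'j') = r_i c_j (N d_ii' - r_i') (N d_jj' - c_j') / (N^2 (N-1))
        rr = r[:-1]
        cc = c[:-1]
        row_part = (np.diag(rr * N) - np.outer(rr, rr))
        col_part = (np.diag(cc * N) - np.outer(cc, cc))
        V += np.kron(row_part, col_part) / (N * N * (N - 1))
        used += 1
    if used == 0:
        raise ValueError("all strata degenerate")
    if skipped:
        logger.info("cmh_general: skipped %d degenerate stratum/strata", skipped)
    rank = int(np.linalg.matrix_rank(V))
    if rank < dim:
        logger.info("cmh_general: singular covariance, df reduced %d -> %d", dim, rank)
        Vinv = np.linalg.pinv(V)
        df = rank
    else:
        Vinv = np.linalg.inv(V)
        df = dim
    stat = float(G @ Vinv @ G)
    p = float(stats.chi2.sf(stat, df=df))
    return CMHResult(statistic=stat, df=df, p=p, arrangement=arrangement,
                     strata_used=used, strata_skipped=skipped)


def per_pair_fisher(array: PairingArray, pre_stratum: str = "pre_GFD",
                    post_stratum: str = "post_GFD",
                    adjust: str = "BH") -> pd.DataFrame:
    """Per-pair 2x2 Fisher exact tests between two condition strata.

    For each gene pair (i, j): ``a`` = pair count pre, ``b`` = other units
    pre, ``c`` = pair count post, ``d`` = other units post.  Odds ratio is
    Haldane-Anscombe corrected (0.5 added to all four cells) whenever any
    cell is zero.  Returns one row per pair with p and adjusted p.
    """
    for s in (pre_stratum, post_stratum):
        if s not in array.strata:
            raise ValueError(f"stratum {s!r} not in array strata {array.strata}")
    if len(array.strata) != 2:
        raise ValueError("per_pair_fisher expects exactly two strata")
    kp = array.strata.index(pre_stratum)
    kq = array.strata.index(post_stratum)
    totals = array.stratum_totals()
    n_pre, n_post = int(totals[kp]), int(totals[kq])
    if n_pre == 0 or n_post == 0:
        raise ValueError("zero-total stratum")

    rows = []
    for i, ga in enumerate(array.row_genes):
        for j, gb in enumerate(array.col_genes):
            a = int(array.counts[i, j, kp])
            c = int(array.counts[i, j, kq])
            b, d = n_pre - a, n_post - c
            if a == 0 and c == 0:
                # pair unobserved anywhere: no evidence either way
                odds, p, direction = 1.0, 1.0, "none"
            else:
                if min(a, b, c, d) == 0:
                    aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                else:
                    aa, bb, cc, dd = a, b, c, d
                odds = (aa * dd) / (bb * cc)
                p = float(stats.fisher_exact([[a, b], [c, d]],
                                             alternative="two-sided")[1])
                direction = ("none" if odds == 1.0
                             else "enriched_post" if odds < 1.0 else "depleted_post")
            rows.append({"gene_a": ga, "gene_b": gb, "a": a, "b": b, "c": c,
                         "d": d, "odds_ratio": float(odds),
                         "log_odds_ratio": float(np.log(odds)),
                         "p": p, "direction": direction})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out


def adjust_pvalues(ps: np.ndarray, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Bonferroni.

    Output order matches input; adjusted values are clipped at 1 and, for
    BH, made monotone in the p-value ordering.
    """
    p = np.asarray(ps, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "BH":
        raise ValueError("method must be 'BH' or 'bonferroni'")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
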