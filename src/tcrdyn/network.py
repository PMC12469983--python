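"""CDR3 similarity clustering into networks of closely related clones.

Clonotypes whose CDR3 amino-acid sequences (TRA chain by default) differ by
few edits are likely to recognize related antigens.  Unique CDR3 sequences
within a group (typically one patient, pooled across conditions) become
nodes; an edge joins two nodes whose normalized Levenshtein similarity
``1 - d(a, b) / max(|a|, |b|)`` reaches the threshold (default 0.85);
clusters are the connected components.  Each node carries the conditions
in which its sequence was observed, so clusters can be classified as
pre-only, post-only or shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

PRE, POST = "pre_GFD", "post_GFD"


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insertions, deletions, substitutions), two-row DP."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized similarity ``1 - d / max(len)`` in [0, 1]; ("", "") -> 1."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein(a, b) / m


_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ORD = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(_AA):
    _AA_ORD[ord(_a)] = _i


def _candidate_pairs(seqs: list[str], threshold: float,
                     block: int = 1024) -> "list[tuple[int, int]]":
    """Pairs (i < j) not excluded by exact edit-distance lower bounds.

    Two bounds: ``d >= |len(a) - len(b)|`` and ``d >= L1(comp_a, comp_b)/2``
    where comp is the 20-dim residue-count vector (a substitution moves the
    composition by L1 distance 2, an indel by 1).  A pair is kept iff the
    bound still allows ``1 - d/max_len >= threshold``, so filtering is
    exactly equivalent to the full scan.
    """
    from scipy.spatial.distance import cdist

    n = len(seqs)
    lens = np.array([len(s) for s in seqs])
    comp = np.zeros((n, 20), dtype=np.float32)
    for i, s in enumerate(seqs):
        codes = _AA_ORD[np.frombuffer(s.encode(), dtype=np.uint8)]
        comp[i] = np.bincount(codes[codes >= 0], minlength=20)
    max_len = np.maximum.outer(lens, lens)
    allowed = (1.0 - threshold) * max_len
    pairs: list[tuple[int, int]] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        l1 = cdist(comp[start:stop], comp, metric="cityblock")
        lb = np.maximum(np.abs(lens[start:stop, None] - lens[None, :]), l1 / 2.0)
        ok = lb <= allowed[start:stop]
        ii, jj = np.nonzero(ok)
        ii = ii + start
        keep = ii < jj
        pairs.extend(zip(ii[keep].tolist(), jj[keep].tolist()))
    return pairs


@dataclass
class CloneGraph:
    graph: nx.Graph           # nodes = unique CDR3 aa; edge attr "similarity"
    nodes: pd.DataFrame       # cdr3, size, status, cluster
    group: str                # label of the grouping this graph was built in

    @property
    def n_clusters(self) -> int:
        return int(self.nodes["cluster"].nunique()) if len(self.nodes) else 0

    def cluster_composition(self) -> pd.DataFrame:
        """Per-cluster node/cell totals and condition-sharing class."""
        if self.nodes.empty:
            return pd.DataFrame(columns=["cluster", "n_nodes", "n_cells", "status"])
        def _status(s: pd.Series) -> str:
            st = set(s)
            return "shared" if len(st) > 1 or st == {"shared"} else st.pop()
        return (self.nodes.groupby("cluster")
                .agg(n_nodes=("cdr3", "size"), n_cells=("size", "sum"),
                     status=("status", _status))
                .reset_index())


def cluster_clones(clonotypes: pd.DataFrame, threshold: float = 0.85,
                   chain: str = "TRA", group: str = "") -> CloneGraph:
    """Build the CDR3 similarity network for one group of clonotypes.

    ``clonotypes`` needs columns ``tra_cdr3_aa``/``trb_cdr3_aa``, ``size``
    and ``condition``.  Sequences are deduplicated (per-cell multiplicity
    is kept as the node weight ``size``); node status reflects the set of
    conditions the sequence occurs in.  An O(n^2) scan with a
    length-difference prefilter (pairs whose length gap alone already
    breaks the threshold are skipped) finds the edges.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    col = {"TRA": "tra_cdr3_aa", "TRB": "trb_cdr3_aa"}[chain]
    if clonotypes.empty:
        empty = pd.DataFrame(columns=["cdr3", "size", "status", "cluster"])
        return CloneGraph(graph=nx.Graph(), nodes=empty, group=group)

    agg = (clonotypes.groupby(col)
           .agg(size=("size", "sum"),
                conds=("condition", lambda s: frozenset(s)))
           .sort_index())
    seqs = list(agg.index)
    status = [
        "shared" if len(c) > 1 else
        ("pre_only" if PRE in c else "post_only" if POST in c else next(iter(c)))
        for c in agg["conds"]
    ]
    g = nx.Graph()
    g.add_nodes_from(seqs)
    for i, j in _candidate_pairs(seqs, threshold):
        sim = similarity(seqs[i], seqs[j])
        if sim >= threshold:
            g.add_edge(seqs[i], seqs[j], similarity=sim)

    cluster_of: dict[str, int] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for node in comp:
            cluster_of[node] = cid
    nodes = pd.DataFrame({
        "cdr3": seqs,
        "size": agg["size"].to_numpy(),
        "status": status,
        "cluster": [cluster_of[s] for s in seqs],
    })
    return CloneGraph(graph=g, nodes=nodes, group=group)


def export_network(graph: CloneGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (source, target, similarity) and node-attribute table."""
    edges = pd.DataFrame(
        [(min(u, v), max(u, v), d["similarity"])
         for u, v, d in graph.graph.edges(data=True)],
        columns=["source", "target", "similarity"],
    ).sort_values(["source", "target"]).reset_index(drop=True)
    return edges, graph.nodes.copy()


def import_network(edges: pd.DataFrame, nodes: pd.DataFrame, group: str = "") -> CloneGraph:
    """Rebuild a CloneGraph from exported tables (round-trip helper)."""
    g = nx.Graph()
    g.add_nodes_from(nodes["cdr3"])
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], similarity=float(row["similarity"]))
    return CloneGraph(graph=g, nodes=nodes.copy(), group=group)
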