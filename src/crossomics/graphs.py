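"""Construction of the heterogeneous cross-omics graph.

The graph ties three molecular layers together: genes, promoter-associated CpG
clusters, and miRNAs.  Two relation types are encoded as typed edges:

* ``g-c``  — a CpG cluster is linked to a gene when the cluster's genomic
  position falls inside the gene's strand-aware promoter span (2,000 bp
  upstream to 500 bp downstream of each annotated transcription start site).
* ``m->g`` — a miRNA is linked to a gene it is predicted to repress, retaining
  interactions whose cumulative weighted context++ score is <= -0.2 (more
  negative = stronger predicted repression).

All coordinates are 0-based half-open internally; readers convert 1-based
(GTF-style) input at the boundary.  The graph is built once from annotation
tables and then shared, unchanged, across all model training runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

RELATION_GC = "g-c"
RELATION_MG = "m->g"
RELATIONS = (RELATION_GC, RELATION_MG)

MODALITY_GENE = "g"
MODALITY_CPG = "c"
MODALITY_MIRNA = "m"
MODALITIES = (MODALITY_GENE, MODALITY_CPG, MODALITY_MIRNA)


# --------------------------------------------------------------------- types
@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss_positions: list[int]
    cross_sample_variance: float = 0.0

    def __post_init__(self):
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id}: tss_positions must be non-empty")


@dataclass
class PromoterSpan:
    """0-based half-open promoter interval derived from one TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    source_tss: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"promoter span for {self.gene_id}: start >= end")


@dataclass
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int
    missing_fraction: float = 0.0

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"probe {self.probe_id}: negative position")


@dataclass
class CpGCluster:
    cluster_id: str
    chrom: str
    member_probe_ids: list[str]
    span_start: int
    span_end: int
    representative_pos: int


@dataclass
class MirnaTargetRecord:
    mirna_id: str
    gene_symbol: str
    context_score: float


@dataclass
class HeteroGraph:
    """Typed node registry plus typed edge lists, with assembly provenance.

    Node tables map stable integer indices to entity ids; edges are stored per
    relation as (src_index, dst_index) integer arrays.  For ``g-c`` the source
    is the CpG cluster and the destination the gene; for ``m->g`` the source is
    the miRNA and the destination the gene.
    """

    gene_ids: list[str]
    cpg_ids: list[str]
    mirna_ids: list[str]
    edges: dict[str, np.ndarray]  # relation -> (E, 2) int array
    edge_weights: dict[str, np.ndarray] = field(default_factory=dict)
    stage_counts: list[dict] = field(default_factory=list)

    def __post_init__(self):
        sizes = {RELATION_GC: (len(self.cpg_ids), len(self.gene_ids)),
                 RELATION_MG: (len(self.mirna_ids), len(self.gene_ids))}
        for rel, arr in self.edges.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            self.edges[rel] = arr
            n_src, n_dst = sizes[rel]
            if arr.size:
                if arr[:, 0].min() < 0 or arr[:, 0].max() >= n_src:
                    raise ValueError(f"{rel}: source index out of range")
                if arr[:, 1].min() < 0 or arr[:, 1].max() >= n_dst:
                    raise ValueError(f"{rel}: destination index out of range")
                if len({tuple(e) for e in arr.tolist()}) != len(arr):
                    raise ValueError(f"{rel}: duplicate edges")
            if rel not in self.edge_weights:
                self.edge_weights[rel] = np.ones(len(arr))

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids) + len(self.cpg_ids) + len(self.mirna_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges.values())

    def node_counts(self) -> dict[str, int]:
        return {"gene": len(self.gene_ids), "cpg": len(self.cpg_ids),
                "mirna": len(self.mirna_ids)}

    def fingerprint(self) -> str:
        """Stable hash of node ids and edge lists; guards checkpoint/graph pairing."""
        h = hashlib.sha256()
        for ids in (self.gene_ids, self.cpg_ids, self.mirna_ids):
            h.update("\x00".join(ids).encode())
            h.update(b"\x01")
        for rel in RELATIONS:
            h.update(rel.encode())
            h.update(np.ascontiguousarray(self.edges[rel]).tobytes())
        return h.hexdigest()[:16]

    def log_stage(self, stage: str, **counts):
        self.stage_counts.append({"stage": stage, **counts})


# ---------------------------------------------------------------- operations
def define_promoter_spans(genes: list[GeneRecord], upstream: int = 2000,
                          downstream: int = 500) -> list[PromoterSpan]:
    """One strand-aware promoter span per (gene, TSS) pair.

    On the + strand the window runs ``[tss - upstream, tss + downstream]``
    (inclusive genomic positions); on the − strand the window mirrors to
    ``[tss - downstream, tss + upstream]``.  Intervals are returned 0-based
    half-open and clipped at zero.  Records with an unknown strand symbol are
    rejected with a logged warning.
    """
    spans: list[PromoterSpan] = []
    for gene in genes:
        if gene.strand not in ("+", "-"):
            logger.warning("gene %s: unknown strand %r, record skipped",
                           gene.gene_id, gene.strand)
            continue
        for tss in gene.tss_positions:
            if gene.strand == "+":
                lo, hi = tss - upstream, tss + downstream
            else:
                lo, hi = tss - downstream, tss + upstream
            spans.append(PromoterSpan(gene_id=gene.gene_id, chrom=gene.chrom,
                                      start=max(lo, 0), end=hi + 1, source_tss=tss))
    return spans


def cluster_probes(probes: list[ProbeRecord], max_gap: int = 500,
                   min_probes: int = 2, max_missing: float = 0.10) -> list[CpGCluster]:
    """Merge nearby methylation probes into CpG clusters.

    Probes with more than ``max_missing`` missing samples are removed first.
    Remaining probes are sorted per chromosome and chained by single linkage:
    adjacent probes at most ``max_gap`` bases apart (inclusive) join the same
    chain.  Chains with fewer than ``min_probes`` members are dropped.  Cluster
    ids are deterministic, derived from chromosome and span.
    """
    kept = [p for p in probes if p.missing_fraction <= max_missing]
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in kept:
        by_chrom.setdefault(p.chrom, []).append(p)

    clusters: list[CpGCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.pos, p.probe_id))
        chain: list[ProbeRecord] = []
        for probe in ordered:
            if chain and probe.pos - chain[-1].pos > max_gap:
                clusters.extend(_finalize_chain(chain, chrom, min_probes))
                chain = []
            chain.append(probe)
        clusters.extend(_finalize_chain(chain, chrom, min_probes))
    return clusters


def _finalize_chain(chain: list[ProbeRecord], chrom: str,
                    min_probes: int) -> list[CpGCluster]:
    if len(chain) < min_probes:
        return []
    start, end = chain[0].pos, chain[-1].pos
    return [CpGCluster(
        cluster_id=f"cpg_{chrom}_{start}_{end}",
        chrom=chrom,
        member_probe_ids=[p.probe_id for p in chain],
        span_start=start,
        span_end=end,
        representative_pos=(start + end) // 2,
    )]


def summarize_cluster_methylation(beta_matrix, probe_ids: list[str],
                                  clusters: list[CpGCluster]) -> np.ndarray:
    """Cluster-level beta values: unweighted mean over member probes per sample.

    ``beta_matrix`` is samples × probes with columns ordered as ``probe_ids``.
    """
    beta = np.asarray(beta_matrix, dtype=float)
    col = {pid: j for j, pid in enumerate(probe_ids)}
    out = np.empty((beta.shape[0], len(clusters)))
    for k, cluster in enumerate(clusters):
        missing = [pid for pid in cluster.member_probe_ids if pid not in col]
        if missing:
            raise KeyError(
                f"cluster {cluster.cluster_id}: probes absent from beta matrix: {missing}")
        cols = [col[pid] for pid in cluster.member_probe_ids]
        out[:, k] = beta[:, cols].mean(axis=1)
    return out


def link_cpg_to_genes(clusters: list[CpGCluster],
                      spans: list[PromoterSpan],
                      mode: str = "representative") -> list[tuple[str, str]]:
    """Cluster→gene promoter links, deduplicated across multi-TSS spans.

    ``mode='representative'`` (default) tests the cluster's single
    representative position against each span; ``mode='any_member'`` is not
    available here because clusters do not carry member positions — the span
    test ``mode='span_overlap'`` instead links when the cluster span intersects
    the promoter interval.
    """
    pairs: set[tuple[str, str]] = set()
    for cluster in clusters:
        for span in spans:
            if cluster.chrom != span.chrom:
                continue
            if mode == "representative":
                hit = span.start <= cluster.representative_pos < span.end
            elif mode == "span_overlap":
                hit = cluster.span_start < span.end and span.start <= cluster.span_end
            else:
                raise ValueError(f"unknown linking mode {mode!r}")
            if hit:
                pairs.add((cluster.cluster_id, span.gene_id))
    return sorted(pairs)


def filter_mirna_targets(records: list[MirnaTargetRecord],
                         score_threshold: float = -0.2,
                         mirna_universe: set[str] | None = None,
                         gene_universe: set[str] | None = None
                         ) -> list[tuple[str, str]]:
    """Confidence-filtered miRNA→gene pairs (score <= threshold, inclusive).

    Pairs are restricted to the retained feature universes when given, and
    duplicates collapsing to the same (miRNA, gene) pair become one edge.
    """
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        if rec.context_score > score_threshold:
            continue
        if mirna_universe is not None and rec.mirna_id not in mirna_universe:
            continue
        if gene_universe is not None and rec.gene_symbol not in gene_universe:
            continue
        pairs.add((rec.mirna_id, rec.gene_symbol))
    return sorted(pairs)


def dedup_by_variance(candidates: list[tuple[str, str, float]]) -> dict[str, str]:
    """One instance per feature id: the one with the largest cross-sample
    variance, ties broken by the lexicographically smallest instance id."""
    best: dict[str, tuple[float, str]] = {}
    for feature_id, instance, variance in candidates:
        key = (-float(variance), instance)
        if feature_id not in best or key < best[feature_id]:
            best[feature_id] = key
    return {fid: inst for fid, (_, inst) in best.items()}


def assemble_graph(genes: list[GeneRecord], clusters: list[CpGCluster],
                   gc_pairs: list[tuple[str, str]],
                   mg_pairs: list[tuple[str, str]],
                   mirna_ids: list[str] | None = None,
                   stage_counts: list[dict] | None = None) -> HeteroGraph:
    """Index entities and turn id-level edge pairs into the final HeteroGraph.

    ``gc_pairs`` are (cluster_id, gene_id); ``mg_pairs`` are
    (mirna_id, gene_symbol-as-gene_id).  Any edge naming an unknown entity is
    an error: filtering to the retained universes must happen upstream.
    """
    gene_ids = sorted({g.gene_id for g in genes})
    cpg_ids = sorted({c.cluster_id for c in clusters})
    if mirna_ids is None:
        mirna_ids = sorted({m for m, _ in mg_pairs})
    gene_ix = {g: i for i, g in enumerate(gene_ids)}
    cpg_ix = {c: i for i, c in enumerate(cpg_ids)}
    mir_ix = {m: i for i, m in enumerate(mirna_ids)}

    def index_pairs(pairs, src_ix, dst_ix, rel):
        out = []
        for src, dst in sorted(set(pairs)):
            if src not in src_ix:
                raise KeyError(f"{rel}: edge references unknown source node {src!r}")
            if dst not in dst_ix:
                raise KeyError(f"{rel}: edge references unknown destination node {dst!r}")
            out.append((src_ix[src], dst_ix[dst]))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    graph = HeteroGraph(
        gene_ids=gene_ids, cpg_ids=cpg_ids, mirna_ids=list(mirna_ids),
        edges={RELATION_GC: index_pairs(gc_pairs, cpg_ix, gene_ix, RELATION_GC),
               RELATION_MG: index_pairs(mg_pairs, mir_ix, gene_ix, RELATION_MG)},
        stage_counts=list(stage_counts or []),
    )
    graph.log_stage("final", genes=len(gene_ids), cpg_clusters=len(cpg_ids),
                    mirnas=len(mirna_ids),
                    gc_edges=len(graph.edges[RELATION_GC]),
                    mg_edges=len(graph.edges[RELATION_MG]))
    return graph


def build_graph(genes: list[GeneRecord], probes: list[ProbeRecord],
                targets: list[MirnaTargetRecord], *, upstream: int = 2000,
                downstream: int = 500, max_gap: int = 500, min_probes: int = 2,
                max_missing: float = 0.10, score_threshold: float = -0.2,
                link_mode: str = "representative") -> tuple[HeteroGraph, list[CpGCluster]]:
    """Full assembly pipeline from annotation tables, with stage accounting."""
    stages: list[dict] = [{"stage": "raw", "genes": len(genes),
                           "probes": len(probes), "target_records": len(targets)}]
    spans = define_promoter_spans(genes, upstream=upstream, downstream=downstream)
    clusters = cluster_probes(probes, max_gap=max_gap, min_probes=min_probes,
                              max_missing=max_missing)
    stages.append({"stage": "filtered", "genes": len(genes),
                   "promoter_spans": len(spans), "cpg_clusters": len(clusters)})
    gene_universe = {g.gene_id for g in genes}
    gc_pairs = link_cpg_to_genes(clusters, spans, mode=link_mode)
    mg_pairs = filter_mirna_targets(targets, score_threshold=score_threshold,
                                    gene_universe=gene_universe)
    mirna_ids = sorted({t.mirna_id for t in targets})
    stages.append({"stage": "harmonized", "gc_edges": len(gc_pairs),
                   "mg_edges": len(mg_pairs), "mirnas": len(mirna_ids)})
    graph = assemble_graph(genes, clusters, gc_pairs, mg_pairs,
                           mirna_ids=mirna_ids, stage_counts=stages)
    return graph, clusters


def degree_preserving_rewire(graph: HeteroGraph, rng: np.random.Generator,
                             swaps_per_edge: int = 10) -> HeteroGraph:
    """Null graph: randomize each relation by repeated double-edge swaps.

    A swap replaces (u1,v1),(u2,v2) with (u1,v2),(u2,v1) when that creates no
    duplicate, so every node keeps its degree under each relation.  Used to
    test whether performance depends on biologically grounded connectivity.
    """
    new_edges = {}
    for rel in RELATIONS:
        edges = [tuple(e) for e in graph.edges[rel].tolist()]
        edge_set = set(edges)
        n = len(edges)
        if n >= 2:
            for _ in range(swaps_per_edge * n):
                i, j = rng.integers(0, n, size=2)
                if i == j:
                    continue
                (u1, v1), (u2, v2) = edges[i], edges[j]
                a, b = (u1, v2), (u2, v1)
                if a in edge_set or b in edge_set or a == b:
                    continue
                edge_set.discard((u1, v1))
                edge_set.discard((u2, v2))
                edge_set.update((a, b))
                edges[i], edges[j] = a, b
        new_edges[rel] = np.asarray(sorted(edges), dtype=np.int64).reshape(-1, 2)
    out = HeteroGraph(gene_ids=list(graph.gene_ids), cpg_ids=list(graph.cpg_ids),
                      mirna_ids=list(graph.mirna_ids), edges=new_edges,
                      stage_counts=list(graph.stage_counts))
    out.log_stage("rewired", gc_edges=len(new_edges[RELATION_GC]),
                  mg_edges=len(new_edges[RELATION_MG]))
    return out


def drop_relation(graph: HeteroGraph, relation: str) -> HeteroGraph:
    """Topological ablation: remove all edges of one relation type."""
    edges = {rel: (np.empty((0, 2), dtype=np.int64) if rel == relation
                   else graph.edges[rel].copy()) for rel in RELATIONS}
    out = HeteroGraph(gene_ids=list(graph.gene_ids), cpg_ids=list(graph.cpg_ids),
                      mirna_ids=list(graph.mirna_ids), edges=edges,
                      stage_counts=list(graph.stage_counts))
    out.log_stage(f"dropped_{relation}", gc_edges=len(edges[RELATION_GC]),
                  mg_edges=len(edges[RELATION_MG]))
    return out


def empty_graph_like(graph: HeteroGraph) -> HeteroGraph:
    """All cross-omics edges removed (fusion-only ablation)."""
    g = drop_relation(graph, RELATION_GC)
    return drop_relation(g, RELATION_MG)


# ----------------------------------------------------------------------- I/O
def save_graph(graph: HeteroGraph, out_dir, params: dict | None = None):
    """Write node tables, relation-tagged edge lists, and JSON metadata."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    for name, ids in (("gene", graph.gene_ids), ("cpg", graph.cpg_ids),
                      ("mirna", graph.mirna_ids)):
        pd.DataFrame({"index": range(len(ids)), "node_id": ids}).to_csv(
            out / f"nodes_{name}.tsv", sep="\t", index=False)
    rel_tag = {RELATION_GC: "gc", RELATION_MG: "mg"}
    src_ids = {RELATION_GC: graph.cpg_ids, RELATION_MG: graph.mirna_ids}
    for rel in RELATIONS:
        e = graph.edges[rel]
        pd.DataFrame({
            "relation": rel,
            "src_id": [src_ids[rel][i] for i in e[:, 0]],
            "dst_id": [graph.gene_ids[j] for j in e[:, 1]],
            "weight": graph.edge_weights[rel],
        }).to_csv(out / f"edges_{rel_tag[rel]}.tsv", sep="\t", index=False)
    meta = {"stage_counts": graph.stage_counts, "fingerprint": graph.fingerprint(),
            "node_counts": graph.node_counts(), "params": params or {}}
    (out / "graph_meta.json").write_text(json.dumps(meta, indent=2))


def load_graph(in_dir) -> HeteroGraph:
    from pathlib import Path
    import pandas as pd
    src = Path(in_dir)
    ids = {}
    for name in ("gene", "cpg", "mirna"):
        tab = pd.read_csv(src / f"nodes_{name}.tsv", sep="\t")
        ids[name] = tab.sort_values("index")["node_id"].astype(str).tolist()
    ix = {"gene": {v: i for i, v in enumerate(ids["gene"])},
          "cpg": {v: i for i, v in enumerate(ids["cpg"])},
          "mirna": {v: i for i, v in enumerate(ids["mirna"])}}
    edges, weights = {}, {}
    for rel, tag, src_type in ((RELATION_GC, "gc", "cpg"), (RELATION_MG, "mg", "mirna")):
        tab = pd.read_csv(src / f"edges_{tag}.tsv", sep="\t")
        edges[rel] = np.asarray(
            [(ix[src_type][s], ix["gene"][d])
             for s, d in zip(tab["src_id"].astype(str), tab["dst_id"].astype(str))],
            dtype=np.int64).reshape(-1, 2)
        weights[rel] = tab["weight"].to_numpy(dtype=float)
    meta_path = src / "graph_meta.json"
    stage_counts = []
    if meta_path.exists():
        stage_counts = json.loads(meta_path.read_text()).get("stage_counts", [])
    return HeteroGraph(gene_ids=ids["gene"], cpg_ids=ids["cpg"],
                       mirna_ids=ids["mirna"], edges=edges, edge_weights=weights,
                       stage_counts=stage_counts)
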