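"""Synthetic annotation fixtures and multi-omics cohorts with planted signal.

The generator emulates the inputs of the real pipeline end to end: stranded
multi-TSS gene models, a methylation probe manifest whose probe placement
induces non-trivial clusters (including dropped singletons and high-missing
probes), a scored miRNA target table straddling the confidence threshold, and
a patient cohort whose subtype signal flows through cross-omics edges:

* each subtype owns a set of *anchor genes* — genes with both a promoter CpG
  cluster and a targeting miRNA — overexpressed in that subtype;
* the anchors' promoter clusters are hypomethylated in proportion to the
  methylation coupling strength (applied on the logit scale, then squashed
  into [0, 1] so beta values stay bounded);
* miRNAs targeting the anchors are upregulated in the subtype, and their
  other (non-anchor) filtered targets are repressed, so the miRNA→gene edges
  connect differentially expressed endpoints.

Optional per-site mean shifts emulate batch structure for site-held-out
protocols.  The generator is a pure function of its configuration: the same
seed yields byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import (CpGCluster, GeneRecord, HeteroGraph, MirnaTargetRecord,
                     ProbeRecord, RELATION_GC, RELATION_MG,
                     build_graph, summarize_cluster_methylation)
from .training import substream

#: cohort class mix with the qualitative ordering of intrinsic-subtype
#: frequencies (Luminal-A-analogue heavy, Normal-like-analogue rarest), at an
#: imbalance mild enough that every class is learnable from 300 patients
DEFAULT_PROPORTIONS = (0.40, 0.22, 0.14, 0.16, 0.08)


@dataclass
class SimConfig:
    n_genes: int = 60
    n_mirnas: int = 25
    n_patients: int = 300
    n_classes: int = 5
    proportions: tuple = DEFAULT_PROPORTIONS
    anchors_per_subtype: int = 3
    effect_size: float = 1.5          # anchor mean shift, in noise-SD units
    methylation_coupling: float = 1.0  # logit-scale hypomethylation per effect unit
    mirna_repression: float = 0.8      # repression of non-anchor targets, SD units
    noise_sd: dict = field(default_factory=lambda: {"g": 1.0, "c": 1.0, "m": 1.0})
    n_sites: int = 3
    site_shift: float = 0.0            # SD of per-site, per-feature mean shifts
    #: fraction of *borderline* patients whose planted effects are attenuated
    #: by ambiguous_scale (tumor purity / borderline phenotypes); keeps the
    #: task learnable-but-imperfect so ablation deltas stay visible
    ambiguous_frac: float = 0.2
    ambiguous_scale: float = 0.35
    #: optional observed-label flips (signal keeps the planted class)
    label_noise: float = 0.0
    probes_per_cluster: tuple = (2, 4)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if len(self.proportions) != self.n_classes:
            raise ValueError("proportions length must equal n_classes")
        if self.effect_size < 0 or self.methylation_coupling < 0:
            raise ValueError("effect sizes must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame        # samples × genes (raw)
    probe_betas: pd.DataFrame       # samples × probes, in [0, 1]
    cluster_betas: pd.DataFrame     # samples × CpG clusters, in [0, 1]
    mirna: pd.DataFrame             # samples × miRNAs (raw)
    labels: np.ndarray              # observed labels (with boundary noise)
    true_labels: np.ndarray         # planted classes driving the signal
    site_labels: np.ndarray
    anchors: dict[int, list[str]]          # subtype -> anchor gene ids
    signal_mirnas: dict[int, list[str]]    # subtype -> upregulated miRNA ids
    planted_edges: dict[int, list[tuple]]  # subtype -> [(relation, src, dst), ...]
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.index)

    def raw_matrices(self) -> dict[str, np.ndarray]:
        return {"g": self.expression.to_numpy(float),
                "c": self.cluster_betas.to_numpy(float),
                "m": self.mirna.to_numpy(float)}


# ---------------------------------------------------------- annotation fixture
def make_annotation_fixture(sim: SimConfig) -> tuple[list[GeneRecord],
                                                     list[ProbeRecord],
                                                     list[MirnaTargetRecord]]:
    """Gene models, probe manifest and scored target table for one config.

    Roughly 85% of genes receive a promoter probe cluster; a handful of
    singleton probes (dropped by the clustering rule), high-missingness probes
    (dropped by the QC rule) and intergenic clusters keep every filter
    exercised.  Target scores straddle the −0.2 confidence cutoff.
    """
    rng = substream(sim.seed, "fixture")
    chroms = [f"chr{c}" for c in range(1, 6)]
    genes: list[GeneRecord] = []
    probes: list[ProbeRecord] = []
    for g in range(sim.n_genes):
        chrom = chroms[g % len(chroms)]
        strand = "+" if g % 2 == 0 else "-"
        base_tss = 50_000 + (g // len(chroms)) * 100_000
        n_tss = int(rng.integers(1, 4))
        tss = sorted(int(base_tss + k * 300) for k in range(n_tss))
        genes.append(GeneRecord(gene_id=f"G{g:03d}", symbol=f"G{g:03d}",
                                chrom=chrom, strand=strand, tss_positions=tss))
        draw = rng.random()
        anchor_tss = tss[0]
        promoter_center = anchor_tss - 800 if strand == "+" else anchor_tss + 800
        if draw < 0.85:  # promoter cluster: 2-4 probes within 500 bp of each other
            k = int(rng.integers(sim.probes_per_cluster[0],
                                 sim.probes_per_cluster[1] + 1))
            for j in range(k):
                probes.append(ProbeRecord(
                    probe_id=f"cg_{g:03d}_{j}", chrom=chrom,
                    pos=promoter_center + j * int(rng.integers(100, 401)),
                    missing_fraction=float(rng.uniform(0, 0.05))))
        elif draw < 0.92:  # singleton probe -> dropped by min_probes
            probes.append(ProbeRecord(probe_id=f"cg_{g:03d}_s", chrom=chrom,
                                      pos=promoter_center,
                                      missing_fraction=float(rng.uniform(0, 0.05))))
        else:  # high-missingness pair -> dropped by QC
            for j in range(2):
                probes.append(ProbeRecord(probe_id=f"cg_{g:03d}_m{j}", chrom=chrom,
                                          pos=promoter_center + j * 200,
                                          missing_fraction=float(rng.uniform(0.11, 0.4))))
        if rng.random() < 0.15:  # intergenic cluster, links to no promoter
            start = base_tss + 20_000
            for j in range(2):
                probes.append(ProbeRecord(probe_id=f"cg_x{g:03d}_{j}", chrom=chrom,
                                          pos=start + j * 250,
                                          missing_fraction=0.0))

    targets: list[MirnaTargetRecord] = []
    gene_ids = [g.gene_id for g in genes]
    for m in range(sim.n_mirnas):
        mirna_id = f"hsa-miR-{m + 100}"
        n_targets = int(rng.integers(3, 9))
        chosen = rng.choice(gene_ids, size=n_targets, replace=False)
        for gid in chosen:
            # ~70% pass the <= -0.2 confidence filter, the rest straddle it
            if rng.random() < 0.7:
                score = float(rng.uniform(-0.6, -0.2))
            else:
                score = float(rng.uniform(-0.19, 0.05))
            targets.append(MirnaTargetRecord(mirna_id=mirna_id, gene_symbol=gid,
                                             context_score=round(score, 4)))
    return genes, probes, targets


def build_fixture_graph(sim: SimConfig) -> tuple[HeteroGraph, list[CpGCluster],
                                                 list[GeneRecord],
                                                 list[ProbeRecord],
                                                 list[MirnaTargetRecord]]:
    genes, probes, targets = make_annotation_fixture(sim)
    graph, clusters = build_graph(genes, probes, targets)
    return graph, clusters, genes, probes, targets


# ------------------------------------------------------------------- cohort
def _balanced_labels(sim: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts from the mixing proportions (largest
    remainder), then a seeded permutation over samples."""
    raw = np.asarray(sim.proportions) * sim.n_patients
    counts = np.floor(raw).astype(int)
    rem = sim.n_patients - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.arange(sim.n_classes), counts)
    return labels[rng.permutation(sim.n_patients)]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_cohort(graph: HeteroGraph, clusters: list[CpGCluster],
                sim: SimConfig) -> SyntheticCohort:
    """Patient cohort with subtype signal planted along cross-omics edges."""
    rng = substream(sim.seed, "cohort")
    n = sim.n_patients
    labels = _balanced_labels(sim, substream(sim.seed, "labels"))
    site_labels = substream(sim.seed, "sites").integers(0, sim.n_sites, size=n)
    # observed labels: a fraction is flipped to another class after the
    # molecular signal has been planted from the true class
    observed = labels.copy()
    if sim.label_noise > 0:
        noise_rng = substream(sim.seed, "labelnoise")
        n_flip = int(round(sim.label_noise * n))
        flip_ix = noise_rng.choice(n, size=n_flip, replace=False)
        shift = noise_rng.integers(1, sim.n_classes, size=n_flip)
        observed[flip_ix] = (labels[flip_ix] + shift) % sim.n_classes
    # borderline patients: planted effects attenuated, labels unchanged
    strength = np.ones(n)
    if sim.ambiguous_frac > 0:
        amb_rng = substream(sim.seed, "ambiguous")
        n_amb = int(round(sim.ambiguous_frac * n))
        strength[amb_rng.choice(n, size=n_amb, replace=False)] = sim.ambiguous_scale

    gene_ix = {g: i for i, g in enumerate(graph.gene_ids)}
    cpg_ix = {c: i for i, c in enumerate(graph.cpg_ids)}
    mir_ix = {m: i for i, m in enumerate(graph.mirna_ids)}
    gc = graph.edges[RELATION_GC]
    mg = graph.edges[RELATION_MG]
    genes_with_cluster = {graph.gene_ids[j] for j in gc[:, 1]}
    genes_with_mirna = {graph.gene_ids[j] for j in mg[:, 1]}
    eligible = sorted(genes_with_cluster & genes_with_mirna)
    need = sim.anchors_per_subtype * sim.n_classes
    if len(eligible) < need:
        raise ValueError(
            f"anchor shortfall: {need} anchors requested but only {len(eligible)} "
            f"genes have both a promoter cluster and a targeting miRNA")
    chosen = substream(sim.seed, "anchors").choice(eligible, size=need, replace=False)
    anchors = {k: sorted(chosen[k * sim.anchors_per_subtype:
                                (k + 1) * sim.anchors_per_subtype].tolist())
               for k in range(sim.n_classes)}

    # per subtype: the miRNAs targeting its anchors, and those miRNAs' other targets
    targets_of = {}   # mirna index -> set of gene indices
    for mi, gi in mg:
        targets_of.setdefault(int(mi), set()).add(int(gi))
    signal_mirnas: dict[int, list[str]] = {}
    for k in range(sim.n_classes):
        anchor_ix = {gene_ix[g] for g in anchors[k]}
        mirs = sorted({graph.mirna_ids[mi] for mi, tg in targets_of.items()
                       if tg & anchor_ix})
        signal_mirnas[k] = mirs

    sd = sim.noise_sd
    expr = rng.normal(0.0, sd["g"], size=(n, len(graph.gene_ids)))
    mirna = rng.normal(0.0, sd["m"], size=(n, len(graph.mirna_ids)))
    probe_ids = sorted({pid for c in clusters for pid in c.member_probe_ids})
    probe_pos = {pid: j for j, pid in enumerate(probe_ids)}
    logit = rng.normal(0.0, sd["c"], size=(n, len(probe_ids)))

    clusters_of_gene: dict[int, list[int]] = {}
    for ci, gi in gc:
        clusters_of_gene.setdefault(int(gi), []).append(int(ci))
    cluster_by_id = {c.cluster_id: c for c in clusters}

    for k in range(sim.n_classes):
        rows = labels == k
        s_k = strength[rows]
        for g in anchors[k]:
            gi = gene_ix[g]
            expr[rows, gi] += sim.effect_size * sd["g"] * s_k
            for ci in clusters_of_gene.get(gi, []):
                cluster = cluster_by_id[graph.cpg_ids[ci]]
                for pid in cluster.member_probe_ids:
                    logit[rows, probe_pos[pid]] -= (sim.methylation_coupling
                                                    * sim.effect_size * s_k)
        anchor_ix = {gene_ix[g] for g in anchors[k]}
        for m in signal_mirnas[k]:
            mi = mir_ix[m]
            mirna[rows, mi] += sim.effect_size * sd["m"] * s_k
            for gi in targets_of.get(mi, ()):  # repress non-anchor targets
                if gi not in anchor_ix:
                    expr[rows, gi] -= sim.mirna_repression * sd["g"] * s_k

    if sim.site_shift > 0:
        site_rng = substream(sim.seed, "siteshift")
        for s in range(sim.n_sites):
            rows = site_labels == s
            expr[rows] += site_rng.normal(0, sim.site_shift, expr.shape[1])
            mirna[rows] += site_rng.normal(0, sim.site_shift, mirna.shape[1])
            logit[rows] += site_rng.normal(0, sim.site_shift, logit.shape[1])

    betas = _sigmoid(logit)
    sample_ids = [f"P{i:04d}" for i in range(n)]
    probe_df = pd.DataFrame(betas, index=sample_ids, columns=probe_ids)
    cluster_mat = summarize_cluster_methylation(
        betas, probe_ids, [cluster_by_id[cid] for cid in graph.cpg_ids])
    planted = {}
    for k in range(sim.n_classes):
        edges = []
        anchor_ix = {gene_ix[g] for g in anchors[k]}
        for ci, gi in gc:
            if int(gi) in anchor_ix:
                edges.append((RELATION_GC, int(ci), int(gi)))
        for mi, gi in mg:
            if graph.mirna_ids[mi] in signal_mirnas[k] and int(gi) in anchor_ix:
                edges.append((RELATION_MG, int(mi), int(gi)))
        planted[k] = edges

    return SyntheticCohort(
        expression=pd.DataFrame(expr, index=sample_ids, columns=graph.gene_ids),
        probe_betas=probe_df,
        cluster_betas=pd.DataFrame(cluster_mat, index=sample_ids,
                                   columns=graph.cpg_ids),
        mirna=pd.DataFrame(mirna, index=sample_ids, columns=graph.mirna_ids),
        labels=observed, true_labels=labels, site_labels=site_labels,
        anchors=anchors,
        signal_mirnas=signal_mirnas, planted_edges=planted, config=sim)


def plant_edge_signal_report(cohort: SyntheticCohort) -> dict:
    """Ground truth for attribution checks: anchors and signal-carrying edges."""
    return {
        "anchors": {int(k): v for k, v in cohort.anchors.items()},
        "signal_mirnas": {int(k): v for k, v in cohort.signal_mirnas.items()},
        "planted_edges": {int(k): [list(e) for e in v]
                          for k, v in cohort.planted_edges.items()},
    }


# ----------------------------------------------------------------------- I/O
def write_fixture(out_dir, genes, probes, targets):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
                   "strand": g.strand,
                   "tss": ";".join(str(t) for t in g.tss_positions)}
                  for g in genes]).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame([{"probe_id": p.probe_id, "chrom": p.chrom, "pos": p.pos,
                   "missing_fraction": p.missing_fraction}
                  for p in probes]).to_csv(out / "probes.tsv", sep="\t", index=False)
    pd.DataFrame([{"mirna_id": t.mirna_id, "gene_symbol": t.gene_symbol,
                   "context_score": t.context_score}
                  for t in targets]).to_csv(out / "targets.tsv", sep="\t", index=False)


def write_cohort(out_dir, cohort: SyntheticCohort):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t")
    cohort.probe_betas.to_csv(out / "probe_betas.tsv", sep="\t")
    cohort.cluster_betas.to_csv(out / "cluster_betas.tsv", sep="\t")
    cohort.mirna.to_csv(out / "mirna.tsv", sep="\t")
    pd.DataFrame({"sample_id": cohort.sample_ids,
                  "subtype": cohort.labels,
                  "site": cohort.site_labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps({"config": cohort.config.to_dict(),
                    **plant_edge_signal_report(cohort)}, indent=2))
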