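"""Readers and writers for annotation tables, omics matrices and labels.

Tabular formats are plain TSV throughout.  Gene models can also be read from
a GTF-dialect file; GTF coordinates are 1-based inclusive and are converted to
the package's internal 0-based convention at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import GeneRecord, MirnaTargetRecord, ProbeRecord


def read_gene_table(path) -> list[GeneRecord]:
    """Gene models from TSV: gene_id, symbol, chrom, strand, tss
    (semicolon-separated for multi-TSS genes), optional cross_sample_variance."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in tab.itertuples(index=False):
        tss = [int(x) for x in str(row.tss).split(";")]
        var = float(getattr(row, "cross_sample_variance", 0.0) or 0.0)
        genes.append(GeneRecord(gene_id=row.gene_id, symbol=row.symbol,
                                chrom=row.chrom, strand=row.strand,
                                tss_positions=tss, cross_sample_variance=var))
    return genes


def read_gene_gtf(path) -> list[GeneRecord]:
    """Gene models from a GTF dialect: one `transcript` feature per TSS.

    The TSS is the transcript start for + strand features and the transcript
    end for − strand features; 1-based inclusive coordinates become 0-based.
    """
    by_gene: dict[str, GeneRecord] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "transcript":
            continue
        chrom, start, end, strand, attrs = fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8]
        attr = {}
        for part in attrs.strip().strip(";").split(";"):
            k, _, v = part.strip().partition(" ")
            attr[k] = v.strip().strip('"')
        gid = attr.get("gene_id", "")
        tss = (start - 1) if strand == "+" else (end - 1)
        if gid in by_gene:
            if tss not in by_gene[gid].tss_positions:
                by_gene[gid].tss_positions.append(tss)
        else:
            by_gene[gid] = GeneRecord(gene_id=gid,
                                      symbol=attr.get("gene_name", gid),
                                      chrom=chrom, strand=strand,
                                      tss_positions=[tss])
    for g in by_gene.values():
        g.tss_positions.sort()
    return [by_gene[k] for k in sorted(by_gene)]


def read_probe_table(path) -> list[ProbeRecord]:
    """Probe manifest TSV: probe_id, chrom, pos, missing_fraction."""
    tab = pd.read_csv(path, sep="\t")
    return [ProbeRecord(probe_id=str(r.probe_id), chrom=str(r.chrom),
                        pos=int(r.pos), missing_fraction=float(r.missing_fraction))
            for r in tab.itertuples(index=False)]


def read_target_table(path) -> list[MirnaTargetRecord]:
    """miRNA target TSV: mirna_id, gene_symbol, context_score."""
    tab = pd.read_csv(path, sep="\t")
    return [MirnaTargetRecord(mirna_id=str(r.mirna_id),
                              gene_symbol=str(r.gene_symbol),
                              context_score=float(r.context_score))
            for r in tab.itertuples(index=False)]


def read_matrix(path) -> pd.DataFrame:
    """Samples × features TSV: header of feature ids, first column sample id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    """Label TSV: sample_id, subtype, optional site."""
    return pd.read_csv(path, sep="\t", index_col=0)


def align_matrix(df: pd.DataFrame, feature_ids: list[str],
                 sample_ids: list[str]) -> np.ndarray:
    """Reindex a matrix to the graph's node ordering and a sample ordering."""
    missing = set(feature_ids) - set(df.columns)
    if missing:
        raise KeyError(f"matrix lacks features: {sorted(missing)[:5]} ...")
    missing_s = set(sample_ids) - set(df.index)
    if missing_s:
        raise KeyError(f"matrix lacks samples: {sorted(missing_s)[:5]} ...")
    return df.loc[sample_ids, feature_ids].to_numpy(dtype=float)
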