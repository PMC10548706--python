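"""Genomic context of a gene family: chromosome distribution, physical gene
clusters, and exon-intron structure statistics.

The cluster rule is a declared operationalisation (the field reports clusters
without a universal definition): a cluster is a maximal run of family-labeled
genes on one chromosome in which each adjacent pair is separated by at most
``max_intervening_genes`` non-family genes AND at most ``max_gap_bp`` base
pairs, with at least ``min_size`` members.  Genes without a family label
never seed or join clusters.  Both limits are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import GeneModel


@dataclass(frozen=True)
class ClusterConfig:
    min_size: int = 3
    max_intervening_genes: int = 10
    max_gap_bp: int = 200_000
    grouping: str = "any_family"  # or "same_family"

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        if self.grouping not in ("any_family", "same_family"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class GeneCluster:
    chromosome: str
    member_gene_ids: list[str]
    family_labels: list[str]
    span: tuple[int, int]

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


@dataclass
class StructureStats:
    gene_id: str
    n_exons: int
    n_introns: int
    intron_phases: list[int]


def chromosome_distribution(
    models: Sequence[GeneModel],
    family_ids: Optional[set[str]] = None,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-chromosome gene counts and density (genes/Mb).

    Counts family genes only when ``family_ids`` is given, otherwise every
    model.  Chromosome lengths default to the maximum gene end observed.
    """
    counted = [
        m for m in models if family_ids is None or m.gene_id in family_ids
    ]
    lengths: dict[str, int] = {}
    for m in models:
        lengths[m.chromosome] = max(lengths.get(m.chromosome, 0), m.end)
    if chromosome_lengths:
        lengths.update(chromosome_lengths)
    rows = []
    by_chrom: dict[str, int] = {}
    for m in counted:
        by_chrom[m.chromosome] = by_chrom.get(m.chromosome, 0) + 1
    for chrom in sorted(by_chrom):
        mb = lengths[chrom] / 1e6
        rows.append(
            {"chromosome": chrom, "n_genes": by_chrom[chrom],
             "genes_per_mb": by_chrom[chrom] / mb}
        )
    return pd.DataFrame(rows, columns=["chromosome", "n_genes", "genes_per_mb"])


def detect_clusters(
    models: Sequence[GeneModel],
    family_labels: Mapping[str, str],
    config: ClusterConfig = ClusterConfig(),
) -> list[GeneCluster]:
    """Find maximal family gene clusters per chromosome.

    ``family_labels`` maps gene id -> family name; genes absent from the map
    are intervening genes.  With ``grouping="same_family"`` adjacent cluster
    members must share a family label.
    """
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.gene_id))
        fam_idx = [i for i, m in enumerate(ordered) if m.gene_id in family_labels]
        run: list[int] = []
        for idx in fam_idx:
            if run:
                prev = run[-1]
                intervening = idx - prev - 1
                gap_bp = max(0, ordered[idx].start - ordered[prev].end)
                same_ok = (
                    config.grouping == "any_family"
                    or family_labels[ordered[idx].gene_id]
                    == family_labels[ordered[prev].gene_id]
                )
                if (
                    intervening <= config.max_intervening_genes
                    and gap_bp <= config.max_gap_bp
                    and same_ok
                ):
                    run.append(idx)
                    continue
                if len(run) >= config.min_size:
                    clusters.append(_make_cluster(chrom, ordered, run, family_labels))
                run = []
            run.append(idx)
        if len(run) >= config.min_size:
            clusters.append(_make_cluster(chrom, ordered, run, family_labels))
    return clusters


def _make_cluster(chrom, ordered, run, family_labels) -> GeneCluster:
    members = [ordered[i] for i in run]
    return GeneCluster(
        chromosome=chrom,
        member_gene_ids=[m.gene_id for m in members],
        family_labels=[family_labels[m.gene_id] for m in members],
        span=(members[0].start, members[-1].end),
    )


def gene_structure_stats(model: GeneModel) -> StructureStats:
    """Intron counts and phases from the CDS segments of a gene model.

    Introns are counted between consecutive CDS segments in transcription
    order; the phase of an intron is the cumulative CDS length upstream of it
    modulo 3 (0/1/2), which is strand-independent because segments are stored
    in transcription order.
    """
    if not model.cds_segments:
        raise ValueError(f"gene {model.gene_id}: no CDS segments")
    lengths = [e - s + 1 for s, e in model.cds_segments]
    phases = []
    cum = 0
    for seg_len in lengths[:-1]:
        cum += seg_len
        phases.append(cum % 3)
    n_exons = len(model.cds_segments)
    return StructureStats(
        gene_id=model.gene_id,
        n_exons=n_exons,
        n_introns=n_exons - 1,
        intron_phases=phases,
    )


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": c.chromosome, "start": c.span[0], "end": c.span[1],
                "n_members": c.n_members,
                "member_ids": ",".join(c.member_gene_ids),
                "families": ",".join(c.family_labels),
            }
            for c in clusters
        ],
        columns=["chromosome", "start", "end", "n_members", "member_ids", "families"],
    )


def structure_stats_to_frame(stats: Sequence[StructureStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "n_exons": s.n_exons, "n_introns": s.n_introns,
                "intron_phases": ",".join(map(str, s.intron_phases)),
            }
            for s in stats
        ],
        columns=["gene_id", "n_exons", "n_introns", "intron_phases"],
    )
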