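"""End-to-end survey: screen -> nomenclature -> context -> duplication ->
Ka/Ks -> expression association, over in-memory objects or files on disk.

This is the composition layer the CLI and the acceptance script drive; each
stage is the corresponding module's public operation, so everything here is
testable piecemeal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import context, duplication, expression, kaks, nomenclature, screen
from .align import align_global
from .io import EvidenceRow, GeneModel, SequenceRecord, write_tsv


@dataclass
class SurveyConfig:
    identification: screen.IdentificationConfig = field(
        default_factory=screen.IdentificationConfig
    )
    nomenclature: nomenclature.NomenclatureConfig = field(
        default_factory=nomenclature.NomenclatureConfig
    )
    cluster: context.ClusterConfig = field(default_factory=context.ClusterConfig)
    synteny: duplication.SyntenyConfig = field(default_factory=duplication.SyntenyConfig)
    evolution: kaks.EvolutionConfig = field(default_factory=kaks.EvolutionConfig)
    association: expression.AssociationConfig = field(
        default_factory=expression.AssociationConfig
    )
    retention: expression.RetentionConfig = field(
        default_factory=expression.RetentionConfig
    )


@dataclass
class SurveyResult:
    screen_results: list[screen.ScreenResult]
    assignments: list[nomenclature.FamilyAssignment]
    classification_summary: pd.DataFrame
    chromosome_table: pd.DataFrame
    clusters: list[context.GeneCluster]
    structure_stats: list[context.StructureStats]
    pairs: list[duplication.AnchorPair]
    blocks: list[duplication.CollinearBlock]
    calls: list[duplication.DuplicationCall]
    evolution: pd.DataFrame
    association: Optional[pd.DataFrame]
    retention: Optional[list[expression.RetentionCall]]

    def kept_ids(self) -> list[str]:
        return [r.id for r in self.screen_results if r.kept]

    def write(self, outdir: str | Path, config: "SurveyConfig") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"tool": "cypkit", "kaks_method": "NG86 (Jukes-Cantor corrected)"}
        screen_rows = pd.DataFrame(
            [
                {
                    "id": r.id, "n_regions": r.profile.n_regions_present,
                    "type": screen.classify_type(r.profile),
                    "kept": r.kept, "reasons": ",".join(r.reasons),
                }
                for r in self.screen_results
            ]
        )
        write_tsv(screen_rows, outdir / "screen.tsv", meta)
        write_tsv(
            nomenclature.assignments_to_frame(self.assignments),
            outdir / "assignments.tsv", meta,
        )
        write_tsv(self.classification_summary, outdir / "classification_summary.tsv", meta)
        write_tsv(self.chromosome_table, outdir / "chromosome_distribution.tsv", meta)
        cluster_meta = dict(
            meta,
            min_size=config.cluster.min_size,
            max_intervening_genes=config.cluster.max_intervening_genes,
            max_gap_bp=config.cluster.max_gap_bp,
        )
        write_tsv(context.clusters_to_frame(self.clusters), outdir / "clusters.tsv", cluster_meta)
        write_tsv(
            context.structure_stats_to_frame(self.structure_stats),
            outdir / "gene_structure.tsv", meta,
        )
        dup_meta = dict(
            meta,
            trd_rule="single-genome: ancestral locus = membership in any collinear block",
        )
        write_tsv(duplication.blocks_to_frame(self.blocks), outdir / "blocks.tsv", dup_meta)
        write_tsv(duplication.calls_to_frame(self.calls), outdir / "duplication_calls.tsv", dup_meta)
        write_tsv(self.evolution, outdir / "kaks.tsv", meta)
        if self.association is not None:
            assoc_meta = dict(
                meta,
                min_fpkm=config.association.min_fpkm,
                stage_rule=config.association.stage_rule,
                alpha=config.association.alpha,
            )
            write_tsv(self.association, outdir / "association.tsv", assoc_meta)
        if self.retention is not None:
            ret_rows = pd.DataFrame(
                [
                    {
                        "gene_1": r.gene_1, "gene_2": r.gene_2,
                        "mechanism": r.mechanism,
                        "r_pair": float("nan") if r.r_pair is None else r.r_pair,
                        "expressed_stages_1": r.expressed_stages_1,
                        "expressed_stages_2": r.expressed_stages_2,
                    }
                    for r in self.retention
                ]
            )
            ret_meta = dict(
                meta,
                expressed_min_fpkm=config.retention.expressed_min_fpkm,
                parallel_r_min=config.retention.parallel_r_min,
            )
            write_tsv(ret_rows, outdir / "retention.tsv", ret_meta)


def run_survey(
    proteins: Sequence[SequenceRecord],
    cds: Sequence[SequenceRecord],
    models: Sequence[GeneModel],
    references: Sequence[nomenclature.ReferenceEntry],
    counts: Optional[pd.DataFrame] = None,
    lengths: Optional[pd.Series] = None,
    replicate_map: Optional[dict] = None,
    metabolites: Optional[pd.DataFrame] = None,
    external_evidence: Sequence[EvidenceRow] = (),
    config: SurveyConfig = SurveyConfig(),
) -> SurveyResult:
    """Run the whole survey over one genome's inputs."""
    ref_records = [
        SequenceRecord(r.id, r.sequence, kind="protein") for r in references
    ]
    screen_results = screen.screen_candidates(
        proteins, external_evidence, config.identification, ref_records
    )
    kept = {r.id for r in screen_results if r.kept}
    prot_map = {r.id: r.sequence for r in proteins}
    cds_map = {r.id: r.sequence for r in cds}

    assignments = [
        nomenclature.assign_family(
            SequenceRecord(gid, prot_map[gid]), references, config.nomenclature
        )
        for gid in sorted(kept)
    ]
    summary = nomenclature.summarize_classification(assignments)
    families = {
        a.query_id: a.family for a in assignments if a.family != "NEW_FAMILY"
    }

    model_map = {m.gene_id: m for m in models}
    chrom_table = context.chromosome_distribution(models, family_ids=set(families))
    clusters = context.detect_clusters(models, families, config.cluster)
    structure = [
        context.gene_structure_stats(model_map[g])
        for g in sorted(families)
        if g in model_map
    ]

    pairs = duplication.find_paralog_pairs(prot_map, families, config.synteny)
    gene_order = duplication.gene_order_from_models(models)
    blocks = duplication.chain_collinear_blocks(pairs, gene_order, config.synteny)
    calls = duplication.classify_modes(pairs, blocks, gene_order, config.synteny)

    evo_rows = []
    calls_with_est: list[tuple[duplication.DuplicationCall, kaks.EvolutionEstimates]] = []
    for call in calls:
        a, b = call.pair.gene_a, call.pair.gene_b
        aln_a, aln_b, _ = align_global(prot_map[a], prot_map[b], config.synteny.scoring)
        codon_aln = kaks.codon_align(
            (aln_a, aln_b),
            kaks.strip_terminal_stop(cds_map[a]),
            kaks.strip_terminal_stop(cds_map[b]),
            a, b,
        )
        est = kaks.ng86(codon_aln)
        calls_with_est.append((call, est))
        evo_rows.append(
            {
                "gene_a": a, "gene_b": b, "mode": call.mode,
                "Ka": est.Ka, "Ks": est.Ks, "ratio": est.ratio,
                "regime": kaks.classify_selection(est),
            }
        )
    evo = pd.DataFrame(
        evo_rows, columns=["gene_a", "gene_b", "mode", "Ka", "Ks", "ratio", "regime"]
    )
    recent = {
        (c.pair.gene_a, c.pair.gene_b)
        for c, _ in kaks.flag_recent_wgd(calls_with_est, config.evolution)
    }
    if len(evo):
        evo["recent_wgd"] = [
            (ga, gb) in recent for ga, gb in zip(evo["gene_a"], evo["gene_b"])
        ]
    else:
        evo["recent_wgd"] = pd.Series(dtype=bool)

    association = None
    retention = None
    if counts is not None and metabolites is not None:
        fpkm = expression.compute_fpkm(counts, lengths, replicate_map)
        fam_fpkm = fpkm.loc[[g for g in fpkm.index if g in families]]
        association = expression.screen_flavonoid_candidates(
            fam_fpkm, metabolites, config.association
        )
        retention = [
            expression.classify_retention(
                call.pair.gene_a,
                fpkm.loc[call.pair.gene_a].to_numpy(),
                call.pair.gene_b,
                fpkm.loc[call.pair.gene_b].to_numpy(),
                config.retention,
            )
            for call in calls
            if call.pair.gene_a in fpkm.index and call.pair.gene_b in fpkm.index
        ]

    return SurveyResult(
        screen_results=screen_results,
        assignments=assignments,
        classification_summary=summary,
        chromosome_table=chrom_table,
        clusters=clusters,
        structure_stats=structure,
        pairs=pairs,
        blocks=blocks,
        calls=calls,
        evolution=evo,
        association=association,
        retention=retention,
    )
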