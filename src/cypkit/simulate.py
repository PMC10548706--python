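"""Synthetic genome, sequence and expression generator with planted truth.

Every pipeline stage is verified against data simulated here: a small
multi-chromosome genome carrying P450-like gene families whose founders have
the four signature regions planted (A or non-A variants per family), family
members diverged from the founders by a codon-level mutation process with
controlled synonymous rate and Ka/Ks, decoy proteins free of all signature
regions, planted whole-genome-duplicated segments, tandem arrays, proximal,
transposed and dispersed copies, and stage-wise expression with planted
retention classes and metabolite-driver genes.

The generator's defaults ARE the stated world for the acceptance checks: a
6 x 40-gene genome, 20 named CYP families spanning the ten clans (eight
WGD pairs in a duplicated 8-gene segment, four tandem, four proximal, four
transposed and four dispersed pairs), divergence under purifying selection
(omega = 0.2), five expression stages with three replicates and five
metabolite-driver genes.  One integer seed drives a single numpy Generator
stream; a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, SequenceRecord, write_fasta, write_gff3, write_tsv
from .kaks import SENSE_CODONS, syn_fraction, translate_cds, translate_codon
from .nomenclature import CLAN_OF_FAMILY, ReferenceEntry
from .screen import DEFAULT_PATTERNS, scan_signatures

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid (sense codons only)
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(translate_codon(_c), []).append(_c)

# per-codon single-base mutation table: (pos, base, new_codon, is_syn, is_stop)
_MUT_TABLE: dict[str, list[tuple[int, str, str, bool, bool]]] = {}
for _c in SENSE_CODONS:
    entries = []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _c[_pos]:
                continue
            _alt = _c[:_pos] + _b + _c[_pos + 1 :]
            _aa = translate_codon(_alt)
            entries.append(
                (_pos, _b, _alt, _aa == translate_codon(_c), _aa is None)
            )
    _MUT_TABLE[_c] = entries


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic genome."""

    n_chromosomes: int = 6
    genes_per_chromosome: int = 40
    gene_pitch_bp: int = 15_000
    protein_length: int = 460  # family proteins (typical P450 ~500 aa)
    decoy_length_range: tuple[int, int] = (250, 400)
    # per-member divergence from the family founder (substitutions/syn site)
    wgd_member_ks: float = 0.10
    local_member_ks: float = 0.03  # tandem and proximal copies (recent)
    trd_member_ks: float = 0.25  # transposed copies (ancient)
    dsd_member_ks: float = 0.15
    omega: float = 0.2  # purifying selection on every planted pair


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Stated world of the expression / metabolite simulation."""

    stages: tuple[str, ...] = ("15DAF", "45DAF", "90DAF", "120DAF", "145DAF")
    n_replicates: int = 3
    library_size: int = 20_000_000
    poisson: bool = True  # negative-binomial overdispersion is out of scope
    # metabolite noise sd as a fraction of the signal sd; calibrated once for
    # ~0.9 per-driver detection power at n=5 stages and frozen
    metabolite_sigma_frac: float = 0.35
    driver_base: tuple[float, ...] = (20.0, 60.0, 110.0, 160.0, 220.0)
    metabolite_scale: float = 0.05  # mg/g flavonoid per driver FPKM unit
    sf_high_fpkm: float = 40.0
    background_mean_log: float = 2.5
    background_sd_log: float = 1.0


@dataclass
class PairTruth:
    gene_a: str
    gene_b: str
    mode: str
    true_ks: float
    true_omega: Optional[float]
    n_syn: int
    n_nonsyn: int
    retention: Optional[str] = None


@dataclass
class GeneTruth:
    gene_id: str
    is_p450: bool
    family: Optional[str]
    subfamily: Optional[str]
    type: Optional[str]  # {"A", "nonA"} for planted P450s
    role: str  # wgd/tandem/proximal/transposed/dispersed/decoy
    cluster_id: Optional[int]
    cds_length: int


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    pairs: list[PairTruth] = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)
    drivers: list[str] = field(default_factory=list)

    def p450_ids(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.is_p450]

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": t.gene_id, "is_p450": t.is_p450,
                    "family": t.family or "", "subfamily": t.subfamily or "",
                    "type": t.type or "", "role": t.role,
                    "cluster_id": -1 if t.cluster_id is None else t.cluster_id,
                    "cds_length": t.cds_length,
                }
                for t in self.genes.values()
            ]
        )

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a, "gene_b": p.gene_b, "mode": p.mode,
                    "true_ks": p.true_ks,
                    "true_omega": np.nan if p.true_omega is None else p.true_omega,
                    "n_syn": p.n_syn, "n_nonsyn": p.n_nonsyn,
                    "retention": p.retention or "",
                }
                for p in self.pairs
            ]
        )


# ---------------------------------------------------------------------------
# Sequence-level primitives


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def random_cds_for_protein(protein: str, rng: np.random.Generator) -> str:
    """A stop-free CDS translating to the protein (random codon choices)."""
    codons = []
    for aa in protein:
        opts = _CODONS_FOR_AA[aa]
        codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def cds_sites(cds: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) NG86 site counts of one CDS."""
    S = sum(syn_fraction(cds[i : i + 3]) for i in range(0, len(cds), 3))
    return S, len(cds) - S


def evolve_cds(
    cds: str,
    ks_target: float,
    omega: float,
    seed_or_rng,
    protected_codons: frozenset[int] = frozenset(),
) -> tuple[str, int, int]:
    """Diverge a CDS by planted synonymous and nonsynonymous substitutions.

    Draws Poisson(ks_target * S) synonymous and Poisson(omega * ks_target * N)
    nonsynonymous single-base events (S, N = NG86 site counts of the input),
    applies them in random order, never creating a stop codon; nonsynonymous
    events avoid ``protected_codons`` (used to keep signature motifs intact).
    Returns (mutated cds, n synonymous events, n nonsynonymous events).
    """
    if ks_target < 0 or omega < 0:
        raise ValueError("ks_target and omega must be non-negative")
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    translate_cds(cds)  # validates stop-free sense codons
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    S, N = cds_sites(cds)
    n_syn = int(rng.poisson(ks_target * S))
    n_nonsyn = int(rng.poisson(omega * ks_target * N))
    events = ["S"] * n_syn + ["N"] * n_nonsyn
    rng.shuffle(events)

    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for kind in events:
        want_syn = kind == "S"
        cands: list[tuple[int, str]] = []
        for ci, codon in enumerate(codons):
            if not want_syn and ci in protected_codons:
                continue
            for _pos, _b, alt, is_syn, is_stop in _MUT_TABLE[codon]:
                if is_stop or is_syn != want_syn:
                    continue
                cands.append((ci, alt))
        if not cands:  # degenerate sequence with no available change
            continue
        ci, alt = cands[rng.integers(len(cands))]
        codons[ci] = alt
    return "".join(codons), n_syn, n_nonsyn


def mutate_protein_to_identity(
    protein: str,
    target_identity: float,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Substitute residues (no indels) to hit a target global identity.

    ``protected`` ranges (0-based half-open) are never touched, so planted
    signature motifs survive.  Realised identity is target +- one residue in
    1/len rounding.
    """
    if not 0 <= target_identity <= 1:
        raise ValueError("target identity must be in [0,1]")
    n_mut = round((1.0 - target_identity) * len(protein))
    blocked = set()
    for s, e in protected:
        blocked.update(range(s, e))
    free = [i for i in range(len(protein)) if i not in blocked]
    if n_mut > len(free):
        raise ValueError("identity target requires mutating protected positions")
    sites = rng.choice(len(free), size=n_mut, replace=False)
    seq = list(protein)
    for si in sites:
        i = free[si]
        alts = [a for a in AA20 if a != seq[i]]
        seq[i] = alts[rng.integers(len(alts))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Founder construction (motif planting)

# motif offsets within a founder protein, in canonical P450 order:
# I-helix < K-helix < PERF < heme, all in the C-terminal half
_MOTIF_OFFSETS = {"ihelix": 285, "khelix": 330, "perf": 395, "heme": 435}


def _motif_instance(region: str, a_type: bool, rng: np.random.Generator) -> str:
    """A concrete residue string matching the region's consensus.

    For non-A founders the instance matches the general pattern but not the
    A-specific one.
    """
    r = lambda: AA20[rng.integers(20)]
    if region == "heme":
        if a_type:  # PFGXGRRXCXG
            return f"PFG{r()}GRR{r()}C{r()}G"
        first = rng.choice([a for a in AA20 if a != "P"])  # breaks the A pattern
        return f"{first}F{r()}{r()}G{r()}R{r()}C{r()}G"
    if region == "perf":
        if a_type:  # FXPERF
            return f"F{r()}PERF"
        mid = rng.choice([a for a in AA20 if a != "E"])
        return f"F{r()}P{mid}R{r()}"
    if region == "ihelix":
        return f"AG{r()}DT" if a_type else f"AG{r()}ET"
    if region == "khelix":
        return f"E{r()}{r()}R"
    raise ValueError(region)


def motif_spans(protein_length: int) -> list[tuple[int, int]]:
    """0-based half-open spans of the four planted signature regions."""
    lengths = {"ihelix": 5, "khelix": 4, "perf": 6, "heme": 11}
    return [(_MOTIF_OFFSETS[k], _MOTIF_OFFSETS[k] + lengths[k]) for k in _MOTIF_OFFSETS]


def make_founder(rng: np.random.Generator, length: int, a_type: bool) -> str:
    """A random protein with the four signature regions planted.

    Rejection-sampled so a non-A founder never carries an accidental
    A-specific match anywhere.
    """
    while True:
        seq = list(random_protein(rng, length))
        for region, off in _MOTIF_OFFSETS.items():
            inst = _motif_instance(region, a_type, rng)
            seq[off : off + len(inst)] = inst
        founder = "".join(seq)
        profile = scan_signatures(founder, DEFAULT_PATTERNS)
        variants = profile.variants()
        if a_type and "A" in variants:
            return founder
        if not a_type and "A" not in variants and "nonA" in variants:
            return founder


def make_decoy(rng: np.random.Generator, length: int) -> str:
    """A random protein with none of the four signature regions."""
    while True:
        seq = random_protein(rng, length)
        if scan_signatures(seq, DEFAULT_PATTERNS).n_regions_present == 0:
            return seq


# ---------------------------------------------------------------------------
# Genome layout (the planted events)

# (family, A-type?, role); roles fix both placement and planted pair modes
_FAMILY_PLAN: list[tuple[str, bool, str]] = [
    ("CYP71", True, "wgd"), ("CYP73", True, "wgd"), ("CYP51", False, "wgd"),
    ("CYP72", False, "wgd"), ("CYP85", False, "wgd"), ("CYP86", False, "wgd"),
    ("CYP97", False, "wgd"), ("CYP710", False, "wgd"),
    ("CYP75", True, "tandem"), ("CYP76", True, "tandem"),
    ("CYP74", False, "tandem"), ("CYP711", False, "tandem"),
    ("CYP78", True, "proximal"), ("CYP81", True, "proximal"),
    ("CYP90", False, "proximal"), ("CYP94", False, "proximal"),
    ("CYP82", True, "dispersed"), ("CYP84", True, "dispersed"),
    ("CYP93", True, "dispersed"), ("CYP98", True, "dispersed"),
]

# transposed copies re-use the first two WGD families (their ancestral locus
# sits inside the duplicated segment)
_TRANSPOSED_HOSTS = ("CYP71", "CYP73")

# (chromosome index, rank) slots; groups separated by >10 intervening genes
# so the only clusters are the two duplicated segments
_WGD_SEGMENT_A = [(0, r) for r in range(5, 13)]  # chr1 ranks 5..12
_WGD_SEGMENT_B = [(1, r) for r in range(8, 16)]  # chr2 ranks 8..15
_TANDEM_SLOTS = {
    "CYP75": [(0, 25), (0, 26)],
    "CYP76": [(1, 28), (1, 29)],
    "CYP74": [(2, 3), (2, 4)],
    "CYP711": [(3, 2), (3, 3)],
}
_PROXIMAL_SLOTS = {
    "CYP78": [(2, 17), (2, 20)],
    "CYP81": [(2, 33), (2, 36)],
    "CYP90": [(4, 5), (4, 8)],
    "CYP94": [(4, 20), (4, 23)],
}
_TRANSPOSED_SLOTS = {"CYP71": (3, 16), "CYP73": (3, 29)}
_DISPERSED_SLOTS = {
    "CYP82": [(0, 39), (5, 5)],
    "CYP84": [(3, 39), (5, 18)],
    "CYP93": [(4, 36), (5, 31)],
    "CYP98": [(4, 39), (5, 39)],
}

_MEMBER_KS_BY_ROLE = {
    "wgd": "wgd_member_ks",
    "tandem": "local_member_ks",
    "proximal": "local_member_ks",
    "transposed": "trd_member_ks",
    "dispersed": "dsd_member_ks",
}


@dataclass
class SimulatedGenome:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    models: list[GeneModel]
    references: list[ReferenceEntry]
    truth: GroundTruth
    config: SimulationConfig

    def protein_map(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.proteins}

    def cds_map(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.cds}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteome.faa")
        write_fasta(self.cds, outdir / "cds.fna")
        write_gff3(self.models, outdir / "genes.gff3")
        from .nomenclature import write_reference_fasta

        write_reference_fasta(self.references, outdir / "references.faa")
        write_tsv(self.truth.genes_frame(), outdir / "truth_genes.tsv")
        write_tsv(self.truth.pairs_frame(), outdir / "truth_pairs.tsv")


def _gene_id(chrom_idx: int, rank: int) -> str:
    return f"g{chrom_idx + 1:02d}_{rank:02d}"


def _build_gene_model(
    gene_id: str,
    chrom: str,
    rank: int,
    cds_len: int,
    pitch: int,
    rng: np.random.Generator,
) -> GeneModel:
    """Place a gene at its rank slot and split its CDS into 1-4 exons."""
    start = 1 + rank * pitch
    n_exons = int(rng.integers(1, 5))
    n_exons = min(n_exons, max(1, cds_len // 60))
    cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0, *map(int, cuts), cds_len]
    seg_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(80, 200)) for _ in range(n_exons - 1)]
    strand = "+" if rng.integers(2) == 0 else "-"
    # genomic layout left-to-right; transcription order follows strand
    genomic_lens = seg_lens if strand == "+" else seg_lens[::-1]
    genomic_introns = introns if strand == "+" else introns[::-1]
    segs = []
    pos = start
    for k, seg_len in enumerate(genomic_lens):
        segs.append((pos, pos + seg_len - 1))
        pos += seg_len
        if k < len(genomic_introns):
            pos += genomic_introns[k]
    end = segs[-1][1]
    tx_segs = segs if strand == "+" else segs[::-1]
    return GeneModel(
        gene_id=gene_id, chromosome=chrom, strand=strand, start=start, end=end,
        exons=list(tx_segs), cds_segments=list(tx_segs),
    )


def simulate_genome(
    config: SimulationConfig = SimulationConfig(), seed: int = 0
) -> SimulatedGenome:
    """Generate the planted genome: proteome, CDS, gene models, references
    and the ground truth used as the acceptance oracle."""
    rng = np.random.default_rng(seed)
    if config.genes_per_chromosome < 40 or config.n_chromosomes < 6:
        raise ValueError(
            "layout needs at least 6 chromosomes x 40 gene slots for the "
            "planted duplication events"
        )

    protected = frozenset(
        ci
        for s, e in motif_spans(config.protein_length)
        for ci in range(s, e)
    )
    member_ks = {role: getattr(config, attr) for role, attr in _MEMBER_KS_BY_ROLE.items()}

    # founders + references
    founders: dict[str, tuple[str, str, bool]] = {}  # family -> (protein, cds, a_type)
    references: list[ReferenceEntry] = []
    for family, a_type, _role in _FAMILY_PLAN:
        prot = make_founder(rng, config.protein_length, a_type)
        cds = random_cds_for_protein(prot, rng)
        founders[family] = (prot, cds, a_type)
        references.append(
            ReferenceEntry(
                id=f"{family}A1_ref",
                sequence=prot,
                clan=CLAN_OF_FAMILY[family],
                family=family,
                subfamily=f"{family}A",
                type="A" if a_type else "nonA",
            )
        )

    # members: gene id -> (family, role, cds, n_syn, n_nonsyn)
    members: dict[str, tuple[str, str, str, int, int]] = {}

    def add_member(family: str, role: str, slot: tuple[int, int]) -> str:
        gid = _gene_id(*slot)
        _prot, cds, _a = founders[family]
        mutated, n_s, n_n = evolve_cds(
            cds, member_ks[role], config.omega, rng, protected_codons=protected
        )
        members[gid] = (family, role, mutated, n_s, n_n)
        return gid

    pair_list: list[tuple[str, str, str]] = []  # (a, b, mode)

    wgd_ids: dict[str, tuple[str, str]] = {}
    for (family, _a, role), slot_a, slot_b in zip(
        [f for f in _FAMILY_PLAN if f[2] == "wgd"], _WGD_SEGMENT_A, _WGD_SEGMENT_B
    ):
        ga = add_member(family, role, slot_a)
        gb = add_member(family, role, slot_b)
        wgd_ids[family] = (ga, gb)
        pair_list.append((ga, gb, "WGD"))
    for family, slots in _TANDEM_SLOTS.items():
        ga, gb = (add_member(family, "tandem", s) for s in slots)
        pair_list.append((ga, gb, "TD"))
    for family, slots in _PROXIMAL_SLOTS.items():
        ga, gb = (add_member(family, "proximal", s) for s in slots)
        pair_list.append((ga, gb, "PD"))
    for family in _TRANSPOSED_HOSTS:
        gt = add_member(family, "transposed", _TRANSPOSED_SLOTS[family])
        for anc in wgd_ids[family]:
            pair_list.append((anc, gt, "TRD"))
    for family, slots in _DISPERSED_SLOTS.items():
        ga, gb = (add_member(family, "dispersed", s) for s in slots)
        pair_list.append((ga, gb, "DSD"))

    # assemble the full gene complement
    truth = GroundTruth()
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    models: list[GeneModel] = []
    cluster_slots = {s: 0 for s in _WGD_SEGMENT_A}
    cluster_slots.update({s: 1 for s in _WGD_SEGMENT_B})
    truth.clusters = [
        [_gene_id(*s) for s in _WGD_SEGMENT_A],
        [_gene_id(*s) for s in _WGD_SEGMENT_B],
    ]

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for rank in range(config.genes_per_chromosome):
            gid = _gene_id(ci, rank)
            if gid in members:
                family, role, cds, n_s, n_n = members[gid]
                prot = translate_cds(cds)
                a_type = founders[family][2]
                truth.genes[gid] = GeneTruth(
                    gene_id=gid, is_p450=True, family=family,
                    subfamily=f"{family}A", type="A" if a_type else "nonA",
                    role=role, cluster_id=cluster_slots.get((ci, rank)),
                    cds_length=len(cds),
                )
            else:
                length = int(rng.integers(*config.decoy_length_range))
                prot = make_decoy(rng, length)
                cds = random_cds_for_protein(prot, rng)
                truth.genes[gid] = GeneTruth(
                    gene_id=gid, is_p450=False, family=None, subfamily=None,
                    type=None, role="decoy", cluster_id=None, cds_length=len(cds),
                )
            proteins.append(SequenceRecord(gid, prot, kind="protein"))
            cds_records.append(SequenceRecord(gid, cds, kind="cds"))
            models.append(
                _build_gene_model(gid, chrom, rank, len(cds), config.gene_pitch_bp, rng)
            )

    # pair truth with realised divergence
    founder_sites = {fam: cds_sites(founders[fam][1]) for fam in founders}
    for ga, gb, mode in pair_list:
        a, b = sorted((ga, gb))
        fam = members[a][0]
        S, N = founder_sites[fam]
        n_syn = members[a][3] + members[b][3]
        n_nonsyn = members[a][4] + members[b][4]
        true_ks = n_syn / S
        true_omega = (n_nonsyn / N) / (n_syn / S) if n_syn else None
        truth.pairs.append(
            PairTruth(a, b, mode, true_ks, true_omega, n_syn, n_nonsyn)
        )

    return SimulatedGenome(
        proteins=proteins, cds=cds_records, models=models,
        references=references, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# Expression + metabolite simulation

# which planted-pair families carry which retention class
_RETENTION_PLAN = {
    "subfunctionalization": ("CYP71", "CYP73", "CYP51", "CYP74"),
    "dosage_balance": ("CYP72", "CYP85", "CYP75", "CYP76"),
    "specialization_or_nonfunctionalization": ("CYP86", "CYP97", "CYP711"),
}
_DRIVER_FAMILIES = ("CYP78", "CYP81", "CYP90", "CYP94", "CYP82")


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame  # genes x (stage, replicate) samples
    lengths: pd.Series
    replicate_map: dict[str, str]
    fpkm_stage: pd.DataFrame  # realised stage-mean FPKM
    metabolites: pd.DataFrame  # stage-indexed: total_flavonoid, component_sum
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts = self.counts.copy()
        counts.insert(0, "length_bp", self.lengths)
        counts.index.name = "gene_id"
        write_tsv(counts.reset_index(), outdir / "counts.tsv")
        met = self.metabolites.copy()
        met.index.name = "stage"
        write_tsv(met.reset_index(), outdir / "metabolites.tsv")


def _planted_profiles(
    truth: GroundTruth, config: ExpressionSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    """Stage-mean FPKM targets per gene, with planted patterns; returns the
    target matrix and the driver gene ids (recorded into truth)."""
    stages = list(config.stages)
    n = len(stages)
    genes = list(truth.genes)
    target = pd.DataFrame(0.0, index=genes, columns=stages)

    pair_by_family: dict[str, PairTruth] = {}
    for p in truth.pairs:
        fam = truth.genes[p.gene_a].family
        # the WGD pair of a transposed host family, not its TRD pairs
        if p.mode in ("WGD", "TD", "PD", "DSD"):
            pair_by_family[fam] = p

    special: set[str] = set()
    half = n // 2 + n % 2
    for mech, fams in _RETENTION_PLAN.items():
        for fam in fams:
            pair = pair_by_family[fam]
            pair.retention = mech
            hi = config.sf_high_fpkm
            if mech == "subfunctionalization":
                e1 = [hi] * half + [0.0] * (n - half)
                e2 = [0.0] * half + [hi] * (n - half)
            elif mech == "dosage_balance":
                base = np.linspace(10.0, 30.0, n)
                e1 = list(base)
                e2 = list(base * 1.4)
            else:  # specialization / nonfunctionalization
                e1 = list(np.linspace(35.0, 55.0, n))
                e2 = [0.0] * n
            target.loc[pair.gene_a] = e1
            target.loc[pair.gene_b] = e2
            special.update((pair.gene_a, pair.gene_b))

    drivers: list[str] = []
    base = np.asarray(config.driver_base, dtype=float)[:n]
    for fam in _DRIVER_FAMILIES:
        pair = pair_by_family[fam]
        gid = pair.gene_a
        scale = float(rng.uniform(0.6, 1.8))
        target.loc[gid] = base * scale
        drivers.append(gid)
        special.add(gid)

    for gid in genes:
        if gid in special:
            continue
        mean = float(np.exp(rng.normal(config.background_mean_log, config.background_sd_log)))
        # smooth non-constant profile: random walk around the mean
        walk = np.cumsum(rng.normal(0.0, 0.35, size=n))
        profile = mean * np.exp(walk - walk.mean())
        target.loc[gid] = np.maximum(profile, 0.05)
    return target, drivers


def simulate_expression(
    truth: GroundTruth,
    config: ExpressionSimConfig = ExpressionSimConfig(),
    seed: int = 0,
) -> SimulatedExpression:
    """Simulate stage-wise counts and a driver-coupled metabolite series.

    Counts are Poisson around FPKM-implied means (or exact rounded means
    with ``poisson=False``); the metabolite series is a linear function of
    the first driver's realised stage-mean FPKM plus Gaussian noise.
    Planted retention classes and driver ids are recorded into ``truth``.
    """
    if len(config.stages) < 3:
        raise ValueError("need at least 3 stages (correlation undefined below)")
    rng = np.random.default_rng(seed)
    target, drivers = _planted_profiles(truth, config, rng)
    truth.drivers = drivers

    genes = list(target.index)
    lengths = pd.Series(
        {g: float(truth.genes[g].cds_length) for g in genes}, name="length_bp"
    )
    samples = [
        f"{stage}_r{rep + 1}"
        for stage in config.stages
        for rep in range(config.n_replicates)
    ]
    replicate_map = {s: s.rsplit("_r", 1)[0] for s in samples}

    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int64)
    for sample in samples:
        stage = replicate_map[sample]
        lam = (
            target[stage].to_numpy()
            * lengths.to_numpy()
            * config.library_size
            / 1e9
        )
        if config.poisson:
            counts[sample] = rng.poisson(lam)
        else:
            counts[sample] = np.round(lam).astype(np.int64)

    totals = counts.sum(axis=0)
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    stage_series = pd.Series(replicate_map)
    fpkm_stage = fpkm.T.groupby(stage_series).mean().T[list(config.stages)]

    driver_fpkm = fpkm_stage.loc[drivers[0]].to_numpy()
    signal = config.metabolite_scale * driver_fpkm
    sigma = config.metabolite_sigma_frac * float(np.std(signal))
    noise_t = rng.normal(0.0, sigma, size=len(signal)) if sigma > 0 else 0.0
    noise_c = rng.normal(0.0, sigma * 0.6, size=len(signal)) if sigma > 0 else 0.0
    metabolites = pd.DataFrame(
        {
            "total_flavonoid": signal + noise_t,
            "component_sum": 0.6 * signal + noise_c,
        },
        index=list(config.stages),
    )

    return SimulatedExpression(
        counts=counts, lengths=lengths, replicate_map=replicate_map,
        fpkm_stage=fpkm_stage, metabolites=metabolites, truth=truth,
    )
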