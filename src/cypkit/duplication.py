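"""Paralog pairs, collinear block chaining and duplication-mode calls.

Gene-family expansion proceeds through five duplication modes: whole-genome
duplication (WGD), tandem (TD), proximal (PD), transposed (TRD) and
dispersed (DSD) duplication.  Modes are assigned per paralog pair with a
fixed precedence WGD > TD > PD > TRD > DSD:

* WGD   - the pair is an anchor inside a collinear block;
* TD    - same chromosome, adjacent gene ranks (0 intervening genes);
* PD    - same chromosome, at most ``proximal_max_intervening`` intervening;
* TRD   - exactly one member sits at an "ancestral" locus, operationalised
          single-genome as membership in any intra-genome collinear block
          (the multi-genome outgroup dating of the original tool is out of
          scope; this simplification is recorded in output metadata);
* DSD   - everything else.

Collinear blocks are maximum-cardinality monotone chains of anchors per
chromosome pair and orientation (longest-increasing-chain dynamic
programming) with rank gaps bounded on both axes; each anchor belongs to at
most one block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentScoring, DEFAULT_SCORING, global_identity

MODES = ("WGD", "TD", "PD", "TRD", "DSD")


@dataclass(frozen=True)
class SyntenyConfig:
    pair_min_identity: float = 0.40
    min_block: int = 5
    max_gene_gap: int = 25
    proximal_max_intervening: int = 10
    scoring: AlignmentScoring = DEFAULT_SCORING

    def __post_init__(self) -> None:
        if self.min_block < 2:
            raise ValueError("min_block must be >= 2")
        if self.proximal_max_intervening < 1:
            raise ValueError("proximal_max_intervening must be >= 1")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("AnchorPair requires gene_a < gene_b (lexicographic)")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def make_pair(gene_a: str, gene_b: str, identity: float, aligned_length: int) -> AnchorPair:
    a, b = sorted((gene_a, gene_b))
    return AnchorPair(a, b, identity, aligned_length)


@dataclass
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # {"same", "inverted"}
    anchors: list[AnchorPair]

    @property
    def score(self) -> int:
        return len(self.anchors)


@dataclass
class DuplicationCall:
    pair: AnchorPair
    mode: str
    evidence: str


def find_paralog_pairs(
    proteins: Mapping[str, str],
    families: Mapping[str, str],
    config: SyntenyConfig = SyntenyConfig(),
) -> list[AnchorPair]:
    """All within-family unordered pairs above the identity floor.

    ``families`` maps gene id -> family label; genes missing from the map or
    labeled NEW_FAMILY are skipped.  Each pair appears once with gene_a <
    gene_b.
    """
    by_family: dict[str, list[str]] = {}
    for gid in sorted(proteins):
        fam = families.get(gid)
        if fam and fam != "NEW_FAMILY":
            by_family.setdefault(fam, []).append(gid)
    pairs: list[AnchorPair] = []
    for fam in sorted(by_family):
        members = by_family[fam]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                ident, ncols = global_identity(proteins[a], proteins[b], config.scoring)
                if ident >= config.pair_min_identity:
                    pairs.append(AnchorPair(a, b, ident, ncols))
    return pairs


# ---------------------------------------------------------------------------
# Collinear chaining


def _best_chain(points: list[tuple[int, int, int]], max_gap: int, inverted: bool):
    """Maximum-cardinality monotone chain over (ra, rb, idx) points.

    Strictly increasing in ra; rb strictly increasing (same) or strictly
    decreasing (inverted); consecutive rank gaps <= max_gap on both axes.
    Ties prefer the chain that is lexicographically first in (ra, rb) order.
    """
    pts = sorted(points, key=lambda p: (p[0], -p[1] if inverted else p[1]))
    n = len(pts)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            ra_j, rb_j, _ = pts[j]
            ra_i, rb_i, _ = pts[i]
            if ra_j >= ra_i or ra_i - ra_j > max_gap:
                continue
            if inverted:
                if rb_j <= rb_i or rb_j - rb_i > max_gap:
                    continue
            else:
                if rb_j >= rb_i or rb_i - rb_j > max_gap:
                    continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if n == 0:
        return []
    # lexicographically-first longest chain: earliest end index wins ties
    end = max(range(n), key=lambda i: (best_len[i], -i))
    chain = []
    while end != -1:
        chain.append(pts[end])
        end = prev[end]
    return chain[::-1]


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    gene_order: Mapping[str, tuple[str, int]],
    config: SyntenyConfig = SyntenyConfig(),
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair / orientation.

    ``gene_order`` maps gene id -> (chromosome, rank along chromosome).
    Blocks are extracted greedily: the longest chain (same orientation first)
    is reported and its anchors removed, until no chain of >= min_block
    anchors remains.  Anchors may belong to at most one block.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for anchor in anchors:
        if anchor.gene_a not in gene_order:
            raise ValueError(f"gene {anchor.gene_a!r} missing from gene_order")
        if anchor.gene_b not in gene_order:
            raise ValueError(f"gene {anchor.gene_b!r} missing from gene_order")
        ca, ra = gene_order[anchor.gene_a]
        cb, rb = gene_order[anchor.gene_b]
        if (cb, rb) < (ca, ra):
            ca, ra, cb, rb = cb, rb, ca, ra
        grouped.setdefault((ca, cb), []).append((ra, rb, anchor))

    blocks: list[CollinearBlock] = []
    bid = 0
    for (ca, cb) in sorted(grouped):
        remaining = list(grouped[(ca, cb)])
        while True:
            best = None
            for orientation in ("same", "inverted"):
                pts = [(ra, rb, i) for i, (ra, rb, _) in enumerate(remaining)]
                chain = _best_chain(pts, config.max_gene_gap, orientation == "inverted")
                if len(chain) >= config.min_block and (
                    best is None or len(chain) > len(best[0])
                ):
                    best = (chain, orientation)
            if best is None:
                break
            chain, orientation = best
            used = [remaining[i] for _, _, i in chain]
            blocks.append(
                CollinearBlock(
                    block_id=bid,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    anchors=[a for _, _, a in used],
                )
            )
            bid += 1
            used_keys = {a.key for _, _, a in used}
            remaining = [t for t in remaining if t[2].key not in used_keys]
    return blocks


def classify_modes(
    pairs: Sequence[AnchorPair],
    blocks: Sequence[CollinearBlock],
    gene_order: Mapping[str, tuple[str, int]],
    config: SyntenyConfig = SyntenyConfig(),
) -> list[DuplicationCall]:
    """Label every paralog pair with exactly one duplication mode."""
    block_anchor: dict[tuple[str, str], int] = {}
    block_genes: set[str] = set()
    for blk in blocks:
        for a in blk.anchors:
            block_anchor[a.key] = blk.block_id
            block_genes.add(a.gene_a)
            block_genes.add(a.gene_b)

    calls: list[DuplicationCall] = []
    for pair in pairs:
        for g in (pair.gene_a, pair.gene_b):
            if g not in gene_order:
                raise ValueError(f"gene {g!r} missing from gene_order")
        ca, ra = gene_order[pair.gene_a]
        cb, rb = gene_order[pair.gene_b]
        if pair.key in block_anchor:
            calls.append(
                DuplicationCall(pair, "WGD", f"anchor_in_block={block_anchor[pair.key]}")
            )
            continue
        if ca == cb:
            intervening = abs(ra - rb) - 1
            if intervening == 0:
                calls.append(DuplicationCall(pair, "TD", "adjacent_ranks"))
                continue
            if intervening <= config.proximal_max_intervening:
                calls.append(DuplicationCall(pair, "PD", f"intervening={intervening}"))
                continue
        in_block = (pair.gene_a in block_genes, pair.gene_b in block_genes)
        if sum(in_block) == 1:
            ancestral = pair.gene_a if in_block[0] else pair.gene_b
            calls.append(DuplicationCall(pair, "TRD", f"ancestral_locus={ancestral}"))
        else:
            calls.append(DuplicationCall(pair, "DSD", "no_other_evidence"))
    return calls


def gene_order_from_models(models) -> dict[str, tuple[str, int]]:
    """Rank every gene along its chromosome by start coordinate."""
    order: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom, ms in by_chrom.items():
        for rank, m in enumerate(sorted(ms, key=lambda x: (x.start, x.end, x.gene_id))):
            order[m.gene_id] = (chrom, rank)
    return order


def calls_to_frame(calls: Sequence[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": c.pair.gene_a, "gene_b": c.pair.gene_b,
                "identity": c.pair.identity, "mode": c.mode, "evidence": c.evidence,
            }
            for c in calls
        ],
        columns=["gene_a", "gene_b", "identity", "mode", "evidence"],
    )


def blocks_to_frame(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                "orientation": b.orientation, "n_anchors": b.score,
                "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
            }
            for b in blocks
        ],
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"],
    )
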