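"""Candidate P450 detection from signature regions.

Cytochrome P450 proteins carry four conserved regions: the heme-binding
motif (the cysteine that coordinates the heme iron), the K-helix, the PERF
region and the I-helix.  The two deep plant clades differ in their consensus
sequences: the A-type (CYP71 clan) consensus is a strict specialisation of
the non-A consensus in each patterned region, so a protein matching an
A-specific pattern is called A-type with precedence.

Consensus language: an uppercase letter is literal, ``X`` matches any
residue (including X itself), and a bracketed group like ``[D/E]`` matches
exactly one of the listed residues.

The candidate screen mirrors a dual-evidence design: a sequence is kept only
if it has both domain-type evidence (signature regions, or an ingested
hmmsearch row under the E-value cap) and similarity evidence (an ingested
BLAST/DIAMOND row under the cap, or internal global identity to a reference
above the configured floor), and is long enough to be a credible P450.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import AlignmentScoring, DEFAULT_SCORING, global_identity
from .io import EvidenceRow, SequenceRecord

REGIONS = ("heme", "khelix", "perf", "ihelix")


@dataclass(frozen=True)
class SignaturePatternSet:
    """The four signature-region consensus patterns, A and non-A variants.

    The K-helix is named in the classification literature but carries no
    printed A/non-A split; the canonical ``EXXR`` consensus is used for both
    and hits there are labelled ``generic``.
    """

    heme_a: str = "PFGXGRRXCXG"
    heme_nonA: str = "XFXXGXRXCXG"
    perf_a: str = "FXPERF"
    perf_nonA: str = "FXPXRX"
    ihelix_a: str = "AGXDT"
    ihelix_nonA: str = "AGX[D/E]T"
    khelix: str = "EXXR"

    def patterns_for(self, region: str) -> tuple[Optional[str], str]:
        """(A-specific pattern or None, general pattern) for a region."""
        return {
            "heme": (self.heme_a, self.heme_nonA),
            "perf": (self.perf_a, self.perf_nonA),
            "ihelix": (self.ihelix_a, self.ihelix_nonA),
            "khelix": (None, self.khelix),
        }[region]


DEFAULT_PATTERNS = SignaturePatternSet()


def parse_consensus(pattern: str) -> list[Optional[frozenset[str]]]:
    """Compile a consensus string to a per-position residue-set list.

    ``None`` marks an any-residue position (``X``).
    """
    if not pattern:
        raise ValueError("empty consensus pattern")
    out: list[Optional[frozenset[str]]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            out.append(frozenset(pattern[i + 1 : j].replace("/", "")))
            i = j + 1
        elif c == "X":
            out.append(None)
            i += 1
        else:
            out.append(frozenset(c))
            i += 1
    return out


def _consensus_to_regex(pattern: str) -> re.Pattern:
    parts = []
    for pos in parse_consensus(pattern):
        parts.append("." if pos is None else "[" + "".join(sorted(pos)) + "]")
    # lookahead so overlapping starts are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass
class SignatureHit:
    start: int  # 0-based
    end: int  # exclusive
    matched_text: str
    variant: str  # {"A", "nonA", "generic"}


@dataclass
class SignatureProfile:
    """Per-region signature hits for one protein."""

    hits: dict[str, list[SignatureHit]] = field(
        default_factory=lambda: {r: [] for r in REGIONS}
    )

    @property
    def n_regions_present(self) -> int:
        return sum(1 for r in REGIONS if self.hits[r])

    def variants(self) -> set[str]:
        return {h.variant for region_hits in self.hits.values() for h in region_hits}


def scan_signatures(
    seq: str, patterns: SignaturePatternSet = DEFAULT_PATTERNS
) -> SignatureProfile:
    """Report every match start of each signature region in a protein.

    A position matching the A-specific consensus is labelled ``A``; one
    matching only the general consensus is ``nonA`` (``generic`` for the
    K-helix, which has a single consensus).  An empty sequence yields a
    zero-hit profile.
    """
    profile = SignatureProfile()
    for region in REGIONS:
        a_pat, general = patterns.patterns_for(region)
        a_sets = parse_consensus(a_pat) if a_pat else None
        rx = _consensus_to_regex(general)
        for m in rx.finditer(seq):
            text = m.group(1)
            start = m.start()
            if a_sets is not None and len(text) == len(a_sets) and all(
                s is None or c in s for c, s in zip(text, a_sets)
            ):
                variant = "A"
            elif a_pat is None:
                variant = "generic"
            else:
                variant = "nonA"
            profile.hits[region].append(
                SignatureHit(start, start + len(text), text, variant)
            )
    return profile


def classify_type(profile: SignatureProfile) -> str:
    """A-type / non-A-type call from a signature profile.

    A-specific matches take precedence (they are strict subsets of the non-A
    patterns, so every A-type protein also matches the general patterns);
    generic K-helix hits alone decide nothing.
    """
    variants = profile.variants()
    if "A" in variants:
        return "A"
    if "nonA" in variants:
        return "nonA"
    return "unclassified"


@dataclass(frozen=True)
class IdentificationConfig:
    min_length: int = 100
    evalue_max: float = 1e-10
    min_regions: int = 1
    similarity_min_identity: float = 0.30
    similarity_min_aligned: int = 150
    scoring: AlignmentScoring = DEFAULT_SCORING

    def __post_init__(self) -> None:
        if not 0 < self.similarity_min_identity < 1:
            raise ValueError("similarity_min_identity must be in (0,1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class ScreenResult:
    id: str
    profile: SignatureProfile
    kept: bool
    reasons: list[str]


def screen_candidates(
    records: Sequence[SequenceRecord],
    external_evidence: Sequence[EvidenceRow],
    config: IdentificationConfig,
    references: Sequence[SequenceRecord],
    patterns: SignaturePatternSet = DEFAULT_PATTERNS,
) -> list[ScreenResult]:
    """Apply the dual-evidence candidate filter to a proteome.

    Kept iff length >= min_length AND domain evidence (>= min_regions
    signature regions, or an ingested domain_scan row with E-value <=
    evalue_max) AND similarity evidence (ingested similarity row under the
    cap, or internal identity >= similarity_min_identity over >=
    similarity_min_aligned columns against any reference).  Rejections carry
    reason codes: too_short, no_domain, no_similarity.
    """
    sim_rows: dict[str, list[EvidenceRow]] = {}
    dom_rows: dict[str, list[EvidenceRow]] = {}
    for row in external_evidence:
        (sim_rows if row.source == "similarity" else dom_rows).setdefault(
            row.query_id, []
        ).append(row)
    if not references and not sim_rows:
        raise ValueError(
            "screen cannot run: no reference sequences and no external "
            "similarity evidence"
        )

    results: list[ScreenResult] = []
    for rec in records:
        profile = scan_signatures(rec.sequence, patterns)
        reasons: list[str] = []
        if len(rec.sequence) < config.min_length:
            reasons.append("too_short")

        has_domain = profile.n_regions_present >= config.min_regions or any(
            r.evalue <= config.evalue_max for r in dom_rows.get(rec.id, [])
        )
        if not has_domain:
            reasons.append("no_domain")

        has_similarity = any(
            r.evalue <= config.evalue_max for r in sim_rows.get(rec.id, [])
        )
        if not has_similarity and not reasons:
            # internal route: only worth aligning when the other filters pass
            for ref in references:
                ident, ncols = global_identity(rec.sequence, ref.sequence, config.scoring)
                if ncols >= config.similarity_min_aligned and ident >= config.similarity_min_identity:
                    has_similarity = True
                    break
        if not has_similarity:
            reasons.append("no_similarity")

        results.append(ScreenResult(rec.id, profile, kept=not reasons, reasons=reasons))
    return results


# ---------------------------------------------------------------------------
# Physicochemical summaries

# Average residue masses (Da), monomer mass minus water.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01528
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

# EMBOSS pKa set
_PKA_POSITIVE = {"nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5}
_PKA_NEGATIVE = {"cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}


@dataclass
class PhysChemSummary:
    length: int
    molecular_weight: float
    isoelectric_point: float


def molecular_weight(seq: str) -> float:
    """Average (not monoisotopic) protein mass in Da; X uses the mean residue mass."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(_RESIDUE_MASS.get(c, _MEAN_RESIDUE_MASS) for c in seq) + _WATER


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    pos = [_PKA_POSITIVE["nterm"]] + [_PKA_POSITIVE[c] for c in seq if c in "HKR"]
    neg = [_PKA_NEGATIVE["cterm"]] + [_PKA_NEGATIVE[c] for c in seq if c in "CDEY"]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - ph)) for pk in neg)
    return charge


def isoelectric_point(seq: str) -> float:
    """pH at which the net charge crosses zero, found by bisection."""
    if not seq:
        raise ValueError("empty sequence")
    if "X" in seq:
        raise ValueError("cannot compute pI for a sequence containing X")
    lo, hi = 0.0, 14.0
    for _ in range(60):  # well past 0.01 pH precision
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(seq: str) -> PhysChemSummary:
    """Length, molecular weight and isoelectric point of a protein."""
    return PhysChemSummary(
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        isoelectric_point=isoelectric_point(seq),
    )
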