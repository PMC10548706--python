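"""Nei-Gojobori (NG86) estimation of Ka, Ks and selection regime.

The method counts, per codon, the fraction of single-base changes that are
synonymous (mutations to stop codons are excluded from the denominators),
averages site counts over the two sequences, counts observed synonymous and
nonsynonymous differences (multi-base codon differences averaged with equal
weight over all orderings of single steps, discarding orderings that pass
through a stop codon), and applies the Jukes-Cantor correction
d = -(3/4)ln(1 - (4/3)p).  A proportion p >= 3/4 is saturated and leaves the
corresponding distance undefined.

Ka/Ks > 1 indicates positive (Darwinian) selection, = 1 neutral evolution,
< 1 purifying selection.  WGD-derived pairs with Ks inside a configurable
window (default [0.15, 0.30], endpoints inclusive) are flagged as candidates
from the recent whole-genome duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .duplication import DuplicationCall

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)

SENSE_CODONS = tuple(sorted(_CODON_AA))  # the 61 sense codons


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon; None for a stop codon."""
    return _CODON_AA.get(codon)


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        aa = translate_codon(cds[i : i + 3])
        if aa is None:
            raise ValueError(f"internal stop codon at nucleotide {i}")
        out.append(aa)
    return "".join(out)


def strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in _STOPS:
        return cds[:-3]
    return cds


def syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Per position, the fraction of the non-stop single-base changes that are
    synonymous; summed over the three positions.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = translate_codon(alt)
            if alt_aa is None:
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons,
    averaged over single-step orderings; orderings through stops discarded
    (all-stop orderings fall back to counting stop steps as nonsynonymous)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops: bool):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = translate_codon(cur), translate_codon(nxt)
            if aa_nxt is None and not allow_stops:
                return None
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff) if (r := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    codons_a: list[str]  # per column: a sense codon or '---'
    codons_b: list[str]

    @property
    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != "---" and cb != "---"
        ]

    @property
    def n_codons_ungapped(self) -> int:
        return len(self.ungapped_columns)


def codon_align(
    protein_aln: tuple[str, str],
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its CDS sequences.

    Each CDS must be exactly 3x the ungapped protein length (terminal stops
    stripped beforehand) and must translate to the protein row; mismatches
    raise with the gene and position named.
    """
    aln_a, aln_b = protein_aln
    if len(aln_a) != len(aln_b):
        raise ValueError("protein alignment rows differ in length")
    out = {gene_a: [], gene_b: []}
    for gene, row, cds in ((gene_a, aln_a, cds_a), (gene_b, aln_b, cds_b)):
        ungapped = row.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{gene}: CDS length {len(cds)} != 3 x protein length {len(ungapped)}"
            )
        k = 0
        for col, aa in enumerate(row):
            if aa == "-":
                out[gene].append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = translate_codon(codon)
            if trans is None:
                raise ValueError(f"{gene}: stop codon at protein position {k}")
            if trans != aa and aa != "X":
                raise ValueError(
                    f"{gene}: codon {codon} at protein position {k} translates to "
                    f"{trans}, alignment says {aa}"
                )
            out[gene].append(codon)
            k += 1
    return CodonAlignment(gene_a, gene_b, out[gene_a], out[gene_b])


@dataclass
class EvolutionEstimates:
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    saturated: bool


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def ng86(aln: CodonAlignment) -> EvolutionEstimates:
    """NG86 Ka/Ks estimates from a codon alignment.

    The ratio is defined only when Ks > 0 and neither proportion is
    saturated (p >= 3/4 under Jukes-Cantor).
    """
    cols = aln.ungapped_columns
    if not cols:
        raise ValueError("empty ungapped codon alignment")
    S = 0.0
    Sd = Nd = 0.0
    for ca, cb in cols:
        S += (syn_fraction(ca) + syn_fraction(cb)) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * len(cols) - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    saturated = Ks is None or Ka is None
    ratio = None
    if not saturated and Ks is not None and Ks > 0 and Ka is not None:
        ratio = Ka / Ks
    return EvolutionEstimates(
        Ka=Ka, Ks=Ks, ratio=ratio, S_sites=S, N_sites=N, Sd=Sd, Nd=Nd,
        saturated=saturated,
    )


def classify_selection(est: EvolutionEstimates, tol: float = 1e-9) -> str:
    """Selection regime from the Ka/Ks ratio."""
    if est.ratio is None:
        return "undefined"
    if est.ratio > 1.0 + tol:
        return "positive"
    if est.ratio >= 1.0 - tol:
        return "neutral"
    return "purifying"


@dataclass(frozen=True)
class EvolutionConfig:
    wgd_ks_window: tuple[float, float] = (0.15, 0.30)

    def __post_init__(self) -> None:
        if self.wgd_ks_window[0] >= self.wgd_ks_window[1]:
            raise ValueError("Ks window low must be < high")


def flag_recent_wgd(
    calls_with_estimates: Sequence[tuple[DuplicationCall, EvolutionEstimates]],
    config: EvolutionConfig = EvolutionConfig(),
) -> list[tuple[DuplicationCall, EvolutionEstimates]]:
    """WGD-mode pairs with Ks inside the window (endpoints inclusive)."""
    lo, hi = config.wgd_ks_window
    return [
        (call, est)
        for call, est in calls_with_estimates
        if call.mode == "WGD" and est.Ks is not None and lo <= est.Ks <= hi
    ]
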