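"""Clan/family/subfamily assignment by pairwise identity to named references.

The CYP nomenclature tiers are identity-based: two P450s sharing more than
40% amino-acid identity belong to the same family, more than 55% to the same
subfamily, and more than 95% are allelic variants; at 40% or less a sequence
may represent a new family.  Inequalities are strict at every threshold.
"Identity" here is percent identity over trimmed global-alignment columns
(see :mod:`cypkit.align`); users preferring another similarity convention can
swap the scoring in the config.

Clan membership is inherited from the best reference (phylogeny-based clan
confirmation is out of scope); when the top three references disagree on the
clan a warning is emitted rather than silently resolved.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .align import AlignmentScoring, DEFAULT_SCORING, global_identity
from .io import SequenceRecord, read_fasta

# Clan membership of the 48 families recorded in the survey's pear genomes:
# the CYP71 clan carries the whole A-type clade (19 families); the remaining
# nine clans hold the 29 non-A families.
CLAN_OF_FAMILY: dict[str, str] = {
    # CYP71 clan (A-type)
    **{f: "CYP71" for f in (
        "CYP71", "CYP73", "CYP75", "CYP76", "CYP77", "CYP78", "CYP79",
        "CYP81", "CYP82", "CYP84", "CYP89", "CYP92", "CYP93", "CYP98",
        "CYP701", "CYP703", "CYP706", "CYP712", "CYP736",
    )},
    # CYP72 clan
    **{f: "CYP72" for f in (
        "CYP72", "CYP714", "CYP715", "CYP721", "CYP734", "CYP735", "CYP749",
    )},
    # CYP85 clan
    **{f: "CYP85" for f in (
        "CYP85", "CYP87", "CYP88", "CYP90", "CYP707", "CYP716", "CYP718",
        "CYP720", "CYP722", "CYP724", "CYP728", "CYP729", "CYP733",
    )},
    # CYP86 clan
    **{f: "CYP86" for f in ("CYP86", "CYP94", "CYP704")},
    # single-family clans
    "CYP51": "CYP51",
    "CYP74": "CYP74",
    "CYP97": "CYP97",
    "CYP710": "CYP710",
    "CYP711": "CYP711",
    "CYP727": "CYP727",
}

TEN_CLANS = (
    "CYP51", "CYP71", "CYP72", "CYP74", "CYP85",
    "CYP86", "CYP97", "CYP710", "CYP711", "CYP727",
)


@dataclass
class ReferenceEntry:
    """A named CYP reference protein with its nomenclature labels."""

    id: str
    sequence: str
    clan: str
    family: str
    subfamily: str
    type: str  # {"A", "nonA"}

    def __post_init__(self) -> None:
        if not self.family.startswith("CYP"):
            raise ValueError(f"reference {self.id}: family {self.family!r} must start with CYP")
        expected = CLAN_OF_FAMILY.get(self.family)
        if expected is not None and expected != self.clan:
            raise ValueError(
                f"reference {self.id}: family {self.family} belongs to clan "
                f"{expected}, not {self.clan}"
            )


@dataclass(frozen=True)
class NomenclatureConfig:
    family_min: float = 0.40
    subfamily_min: float = 0.55
    allelic_min: float = 0.95
    scoring: AlignmentScoring = DEFAULT_SCORING

    def __post_init__(self) -> None:
        if not 0 < self.family_min < self.subfamily_min < self.allelic_min < 1:
            raise ValueError("thresholds must satisfy 0 < family < subfamily < allelic < 1")


@dataclass
class FamilyAssignment:
    query_id: str
    best_ref_id: str
    identity: float
    aligned_length: int
    clan: str
    family: str  # family name or "NEW_FAMILY"
    subfamily: Optional[str]
    allelic_variant: bool
    type: str


def read_reference_fasta(path: str | Path) -> list[ReferenceEntry]:
    """Read a labeled reference FASTA.

    Header labels: ``>id clan=CYP71 family=CYP71 subfamily=CYP71A type=A``.
    """
    entries = []
    for rec in read_fasta(path, kind="protein"):
        labels = dict(re.findall(r"(\w+)=(\S+)", rec.description))
        missing = {"clan", "family", "subfamily", "type"} - set(labels)
        if missing:
            raise ValueError(f"reference {rec.id}: missing header labels {sorted(missing)}")
        entries.append(
            ReferenceEntry(
                id=rec.id,
                sequence=rec.sequence,
                clan=labels["clan"],
                family=labels["family"],
                subfamily=labels["subfamily"],
                type=labels["type"],
            )
        )
    return entries


def write_reference_fasta(entries: Sequence[ReferenceEntry], path: str | Path) -> None:
    from .io import write_fasta

    recs = [
        SequenceRecord(
            e.id,
            e.sequence,
            kind="protein",
            description=f"clan={e.clan} family={e.family} subfamily={e.subfamily} type={e.type}",
        )
        for e in entries
    ]
    write_fasta(recs, path)


def assign_family(
    query: SequenceRecord,
    references: Sequence[ReferenceEntry],
    config: NomenclatureConfig = NomenclatureConfig(),
) -> FamilyAssignment:
    """Assign a query protein to a nomenclature tier via its best reference.

    The best reference maximises identity (ties: longer aligned length, then
    lexicographic reference id).  Strictly above the allelic threshold the
    query is an allelic variant of the best reference's subfamily; above the
    subfamily threshold it joins the subfamily; above the family threshold
    the family only; at or below the family threshold it is a NEW_FAMILY
    call with clan ``unassigned``.
    """
    if not references:
        raise ValueError("assign_family requires at least one reference")
    scored = []
    for ref in sorted(references, key=lambda r: r.id):
        ident, ncols = global_identity(query.sequence, ref.sequence, config.scoring)
        scored.append((ident, ncols, ref))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].id))
    identity, ncols, best = scored[0]

    # neighbor-consistency check: only neighbors that themselves clear the
    # family threshold can vote on the clan
    top_clans = {
        ref.clan for ident, _, ref in scored[:3] if ident > config.family_min
    }
    if identity > config.family_min and len(top_clans) > 1:
        warnings.warn(
            f"query {query.id}: top references disagree on clan ({sorted(top_clans)})",
            stacklevel=2,
        )

    if identity > config.allelic_min:
        family, subfamily, allelic = best.family, best.subfamily, True
    elif identity > config.subfamily_min:
        family, subfamily, allelic = best.family, best.subfamily, False
    elif identity > config.family_min:
        family, subfamily, allelic = best.family, None, False
    else:
        return FamilyAssignment(
            query_id=query.id,
            best_ref_id=best.id,
            identity=identity,
            aligned_length=ncols,
            clan="unassigned",
            family="NEW_FAMILY",
            subfamily=None,
            allelic_variant=False,
            type="unclassified",
        )
    return FamilyAssignment(
        query_id=query.id,
        best_ref_id=best.id,
        identity=identity,
        aligned_length=ncols,
        clan=best.clan,
        family=family,
        subfamily=subfamily,
        allelic_variant=allelic,
        type=best.type,
    )


def summarize_classification(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    """Count table per (clan, family): n_genes, n_A, n_nonA, plus a totals row.

    The totals row carries the A-type share as a percentage of all genes.
    """
    rows = []
    by_key: dict[tuple[str, str], list[FamilyAssignment]] = {}
    for a in assignments:
        by_key.setdefault((a.clan, a.family), []).append(a)
    for (clan, family), members in sorted(by_key.items()):
        n_a = sum(1 for m in members if m.type == "A")
        n_non = sum(1 for m in members if m.type == "nonA")
        rows.append(
            {"clan": clan, "family": family, "n_genes": len(members),
             "n_A": n_a, "n_nonA": n_non, "pct_A": 100.0 * n_a / len(members)}
        )
    total = len(assignments)
    total_a = sum(1 for a in assignments if a.type == "A")
    total_non = sum(1 for a in assignments if a.type == "nonA")
    rows.append(
        {"clan": "TOTAL", "family": "TOTAL", "n_genes": total, "n_A": total_a,
         "n_nonA": total_non, "pct_A": (100.0 * total_a / total) if total else 0.0}
    )
    return pd.DataFrame(rows, columns=["clan", "family", "n_genes", "n_A", "n_nonA", "pct_A"])


def assignments_to_frame(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id, "best_ref": a.best_ref_id,
                "identity": a.identity, "aligned_length": a.aligned_length,
                "clan": a.clan, "family": a.family,
                "subfamily": a.subfamily or "", "allelic": a.allelic_variant,
                "type": a.type,
            }
            for a in assignments
        ]
    )
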