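"""Global identity, threshold tiers, classification summaries."""

import itertools

import numpy as np
import pytest

from cypkit.align import (
    AlignmentScoring,
    align_global,
    global_identity,
    identity_from_alignment,
    _load_matrix,
)
from cypkit.io import SequenceRecord
from cypkit.nomenclature import (
    CLAN_OF_FAMILY,
    FamilyAssignment,
    NomenclatureConfig,
    ReferenceEntry,
    assign_family,
    read_reference_fasta,
    summarize_classification,
    write_reference_fasta,
)
from cypkit.simulate import motif_spans, mutate_protein_to_identity

AAS = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# exhaustive alignment oracle (independent of the DP implementation)


def enumerate_best_alignment(a: str, b: str, scoring: AlignmentScoring):
    """First optimal global alignment in diagonal>up>left preference order,
    found by exhaustive enumeration of every monotone alignment path.

    Paths are generated backwards from (len(a), len(b)); at each point the
    diagonal branch is explored first, then up, then left, so the first
    maximal-score path matches the DP traceback's documented tie-break.
    Scores are computed forward over the finished path, independently of any
    DP recurrence.
    """
    alphabet, S = _load_matrix(scoring.matrix)
    idx = {c: i for i, c in enumerate(alphabet)}

    def score(path):
        total = 0
        prev = None
        for op, i, j in path:
            if op == "D":
                total += S[idx[a[i]], idx[b[j]]]
            else:
                total += -scoring.gap_extend if prev == op else -scoring.gap_open
            prev = op
        return total

    best = None
    stack = [(len(a), len(b), [])]
    while stack:
        i, j, path = stack.pop()
        if i == 0 and j == 0:
            s = score(path)
            if best is None or s > best[0]:
                best = (s, path)
            continue
        # push in reverse so diagonal is explored first (LIFO)
        if j > 0:
            stack.append((i, j - 1, [("L", i, j - 1)] + path))
        if i > 0:
            stack.append((i - 1, j, [("U", i - 1, j)] + path))
        if i > 0 and j > 0:
            stack.append((i - 1, j - 1, [("D", i - 1, j - 1)] + path))
    s, path = best
    aln_a = "".join(a[i] if op != "L" else "-" for op, i, j in path)
    aln_b = "".join(b[j] if op != "U" else "-" for op, i, j in path)
    return aln_a, aln_b, s


class TestGlobalIdentity:
    def test_self_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = "".join(rng.choice(AAS, size=rng.integers(5, 120)))
            ident, ncols = global_identity(s, s)
            assert ident == 1.0 and ncols == len(s)

    def test_three_quarters(self):
        ident, ncols = global_identity("AAAA", "AAAT")
        assert ident == pytest.approx(0.75) and ncols == 4

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = "".join(rng.choice(AAS, size=rng.integers(3, 60)))
            y = "".join(rng.choice(AAS, size=rng.integers(3, 60)))
            assert global_identity(x, y) == pytest.approx(global_identity(y, x))

    def test_matches_exhaustive_enumeration_small(self):
        """DP alignment equals exhaustive path enumeration on short pairs."""
        rng = np.random.default_rng(4)
        scoring = AlignmentScoring()
        for _ in range(40):
            a = "".join(rng.choice(AAS, size=rng.integers(1, 7)))
            b = "".join(rng.choice(AAS, size=rng.integers(1, 7)))
            oa, ob, oscore = enumerate_best_alignment(a, b, scoring)
            da, db, dscore = align_global(a, b, scoring)
            assert dscore == oscore, (a, b)
            assert (da, db) == (oa, ob), (a, b)

    def test_x_never_identical(self):
        ident, _ = global_identity("AXA", "AXA")
        assert ident == pytest.approx(2 / 3)

    def test_terminal_gap_trimming(self):
        ident, ncols = identity_from_alignment("--AAAA", "TTAAAA")
        assert ident == 1.0 and ncols == 4


def _reference_set(rng):
    """Small labeled reference panel built on motif-bearing founders."""
    from cypkit.simulate import make_founder

    refs = []
    for family, a_type in (("CYP71", True), ("CYP75", True), ("CYP97", False)):
        seq = make_founder(rng, 460, a_type)
        refs.append(
            ReferenceEntry(
                id=f"{family}A1_ref", sequence=seq, clan=CLAN_OF_FAMILY[family],
                family=family, subfamily=f"{family}A", type="A" if a_type else "nonA",
            )
        )
    return refs


class TestAssignFamily:
    def test_tier_examples(self):
        rng = np.random.default_rng(8)
        refs = _reference_set(rng)
        spans = motif_spans(460)
        cases = [(0.97, "allelic"), (0.75, "subfamily"), (0.48, "family"), (0.30, "new")]
        for target, tier in cases:
            query = SequenceRecord(
                "q", mutate_protein_to_identity(refs[1].sequence, target, rng, spans)
            )
            a = assign_family(query, refs)
            if tier == "allelic":
                assert a.allelic_variant and a.subfamily == "CYP75A"
            elif tier == "subfamily":
                assert not a.allelic_variant and a.subfamily == "CYP75A"
            elif tier == "family":
                assert a.family == "CYP75" and a.subfamily is None
            else:
                assert a.family == "NEW_FAMILY" and a.clan == "unassigned"

    def test_tier_monotone_in_identity(self):
        """The assignment tier never decreases as identity increases."""
        rng = np.random.default_rng(12)
        refs = _reference_set(rng)
        spans = motif_spans(460)
        rank = {"NEW_FAMILY": 0, "family": 1, "subfamily": 2, "allelic": 3}

        def tier(a: FamilyAssignment) -> int:
            if a.family == "NEW_FAMILY":
                return 0
            if a.allelic_variant:
                return 3
            return 2 if a.subfamily else 1

        last = -1
        for target in (0.30, 0.48, 0.62, 0.80, 0.97):
            q = SequenceRecord("q", mutate_protein_to_identity(refs[0].sequence, target, rng, spans))
            t = tier(assign_family(q, refs))
            assert t >= last
            last = t

    def test_reference_order_invariance(self):
        rng = np.random.default_rng(13)
        refs = _reference_set(rng)
        q = SequenceRecord(
            "q", mutate_protein_to_identity(refs[2].sequence, 0.7, rng, motif_spans(460))
        )
        a1 = assign_family(q, refs)
        a2 = assign_family(q, refs[::-1])
        assert (a1.best_ref_id, a1.family, a1.subfamily) == (
            a2.best_ref_id, a2.family, a2.subfamily,
        )

    def test_empty_references(self):
        with pytest.raises(ValueError):
            assign_family(SequenceRecord("q", "MKV"), [])

    def test_threshold_config_validation(self):
        with pytest.raises(ValueError):
            NomenclatureConfig(family_min=0.6, subfamily_min=0.5)


class TestSummary:
    def test_empty(self):
        table = summarize_classification([])
        assert table.iloc[-1]["n_genes"] == 0

    def _fake(self, n, typ):
        return [
            FamilyAssignment(f"g{typ}{i}", "r", 0.8, 400, "CYP71" if typ == "A" else "CYP85",
                             "CYP71" if typ == "A" else "CYP85", None, False, typ)
            for i in range(n)
        ]

    def test_a_share_printed_cohort(self):
        """A cohort split 152 A / 186 non-A gives a 45.0% A-type share."""
        table = summarize_classification(self._fake(152, "A") + self._fake(186, "nonA"))
        total = table.iloc[-1]
        assert total["n_genes"] == 338
        assert total["pct_A"] == pytest.approx(45.0, abs=0.05)

    def test_matches_truth_histogram(self, default_genome, survey_result):
        """Per-family counts equal the generator's planted family histogram."""
        truth_counts = {}
        for t in default_genome.truth.genes.values():
            if t.is_p450:
                truth_counts[t.family] = truth_counts.get(t.family, 0) + 1
        table = summarize_classification(survey_result.assignments)
        got = {
            row.family: row.n_genes
            for row in table.itertuples()
            if row.family not in ("TOTAL", "NEW_FAMILY")
        }
        assert got == truth_counts


class TestReferenceIO:
    def test_header_round_trip(self, tmp_path):
        rng = np.random.default_rng(30)
        refs = _reference_set(rng)
        p = tmp_path / "refs.faa"
        write_reference_fasta(refs, p)
        back = read_reference_fasta(p)
        assert [(r.id, r.clan, r.family, r.subfamily, r.type) for r in back] == [
            (r.id, r.clan, r.family, r.subfamily, r.type) for r in refs
        ]

    def test_clan_map_consistency(self):
        with pytest.raises(ValueError, match="clan"):
            ReferenceEntry("r", "MKV", clan="CYP85", family="CYP71",
                           subfamily="CYP71A", type="A")
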