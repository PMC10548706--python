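# Methods

This note documents the models, conventions and defaults behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the design choices made where the field's practice is not
uniquely determined.

## Signature-region screen

A protein qualifies as a P450 candidate when it carries the conserved
regions that define the superfamily.  Four regions are scanned with
consensus patterns (`X` = any residue, `[D/E]` = one of the listed
residues):

| region  | A-type        | non-A-type     |
|---------|---------------|----------------|
| heme    | `PFGXGRRXCXG` | `XFXXGXRXCXG`  |
| PERF    | `FXPERF`      | `FXPXRX`       |
| I-helix | `AGXDT`       | `AGX[D/E]T`    |
| K-helix | `EXXR` (no published A/non-A split) |

Every A-type pattern is a strict specialisation of its non-A counterpart
(a tested containment property), so typing uses precedence: any A-specific
hit ⇒ A-type; otherwise any non-A hit ⇒ non-A; K-helix hits are labelled
`generic` and never decide the type.  The K-helix consensus is the
canonical `EXXR` of the P450 literature and is configurable, since the
classification sources name the region without printing a pattern.

The candidate filter mirrors a dual-evidence design: keep a sequence iff

* length ≥ 100 residues (shorter sequences are fragments), AND
* domain evidence: ≥ 1 signature region, or an ingested hmmsearch
  `--domtblout` row with E-value ≤ 1e−10, AND
* similarity evidence: an ingested BLAST/DIAMOND outfmt-6 row with
  E-value ≤ 1e−10, or internal global identity ≥ 30 % over ≥ 150 aligned
  columns against any reference P450.

The internal identity route substitutes for a DIAMOND E-value when no
external search output is available: E-values are not computable without
the external tool's statistics, but the *structure* of the filter (an
intersection of two independent evidence types) is preserved.  Every
rejection carries a reason code (`too_short`, `no_domain`,
`no_similarity`).

Molecular weight uses average residue masses plus one water; `X` uses the
mean residue mass and blocks pI.  The isoelectric point solves
net-charge(pH) = 0 by bisection under a Henderson–Hasselbalch model with
the EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1), iterated well past the 0.01-pH target so the
residual charge is < 1e−3.

## Nomenclature

CYP naming is identity-tiered: strictly above 40 % pairwise amino-acid
identity ⇒ same family, above 55 % ⇒ same subfamily, above 95 % ⇒ allelic
variants; at or below 40 % a query is reported `NEW_FAMILY`.  The sources
alternate between "similarity" and "identity"; this package implements
percent identity over global-alignment columns after trimming
terminal-gap columns, which is reproducible without a scoring-dependent
similarity definition (the thresholds are configurable for users who
prefer another convention, and the inequalities are strict, following
"more than / greater than / exceeds").

Alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open 10,
extend 1), JIT-compiled, with a fixed traceback tie-break (diagonal, then
up, then left — the lexicographically first optimal path, reproduced
exactly by the test suite's exhaustive-enumeration oracle).  Identity is
symmetric by construction (the pair is aligned in canonical order).  `X`
is scored by the matrix but never counts as identical.

Clan labels are inherited from the best reference through a bundled
clan↔family map covering the ten clans and 48 families of the surveyed
genomes; tree-based clan confirmation is out of scope.  When the top
three references that clear the family threshold disagree on the clan, a
warning is emitted rather than silently resolved.  Best-reference ties
break by higher aligned length, then lexicographic reference id, so
classification is invariant to reference order.

## Genome context

The literature reports P450 gene clusters without a universal rule; the
rule here is declared and recorded in output metadata: a cluster is a
maximal run of ≥ 3 family-assigned genes on one chromosome where adjacent
members are separated by ≤ 10 intervening genes AND ≤ 200 kb.  Unassigned
genes never seed or join clusters.  Intron phase is defined on CDS (not
UTR-containing exons) as the cumulative upstream CDS length mod 3, which
is strand-independent because segments are stored in transcription order.

## Duplication modes

Within-family pairs with identity ≥ 0.40 are the paralog set.  Collinear
blocks are maximum-cardinality monotone chains of anchors per chromosome
pair and orientation, with rank gaps ≤ 25 on both axes and ≥ 5 anchors
per block; anchors join at most one block (greedy extraction, longest
chain first, same orientation before inverted).  Modes follow precedence:

* **WGD** — the pair is an anchor inside a collinear block;
* **TD** — same chromosome, adjacent ranks (0 intervening genes);
* **PD** — same chromosome, ≤ 10 intervening genes;
* **TRD** — exactly one member sits at an ancestral locus;
* **DSD** — everything else.

Proper transposed-duplication dating needs outgroup genomes; the
single-genome simplification used here defines "ancestral locus" as
membership in any intra-genome collinear block, and is recorded in output
metadata.  When only family proteins (not a full proteome) are supplied,
blocks are built from family anchors alone — a power loss, not an error.

## Ka/Ks (NG86)

The estimator is Nei–Gojobori with equal-weight pathway averaging:

* per codon, each position contributes `syn/valid` synonymous sites,
  where `valid` counts the non-stop single-base changes (mutations to
  stops are excluded from denominators; counting them as nonsynonymous is
  the common alternative and is not implemented);
* site counts are averaged over the two sequences, so
  S + N = 3 × ungapped codons exactly;
* codons differing at k positions average Sd/Nd over all k! orderings of
  single steps, discarding orderings that pass through a stop codon
  (if every ordering does, stop-passing steps count as nonsynonymous);
* ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 sets a `saturated` flag and leaves
  the distance undefined rather than clipping;
* ω = Ka/Ks is defined only when Ks > 0 and nothing is saturated;
  ω > 1 positive, = 1 (±1e−9) neutral, < 1 purifying.

NG86 stands in for the GMYN estimator used with KaKs_Calculator in
comparable surveys: NG86 is fully specified, oracle-checkable by
exhaustive mutation enumeration, and adequate at the low-to-moderate
divergences the synthetic world plants.  The substitution is stated in
output metadata.  WGD pairs with Ks in [0.15, 0.30] (endpoints inclusive,
per "between") are flagged as candidates from the recent whole-genome
duplication.

## Expression association

FPKM[g,s] = counts[g,s]·10⁹ / (length[g]·total[s]); biological replicates
are averaged after per-sample normalisation (three replicates by
default).  The candidate screen:

1. removes genes whose **maximum** stage FPKM is < 10 (a gene strongly
   expressed in one stage survives; the mean is a config alternative —
   which summary the comparable surveys filtered on is not stated);
2. stage 1: two-sided Pearson p < 0.05 against the total-flavonoid
   series (the published stage-1 criterion is not printed; the printed
   stage-2 criterion is mirrored);
3. stage 2: the same test against the sum of the three major flavonoid
   components; the intersection is the candidate set.

p-values are raw, matching practice in such surveys; Benjamini–Hochberg
q-values are reported as extra columns for users.  Genes with constant
expression across stages have undefined correlation and are excluded from
the tested set (reported with a `constant` flag) rather than failing the
whole screen; `pearson_two_sided` itself raises on constant input.

Retention classes quantify qualitative descriptions; thresholds are
config and recorded in metadata.  A copy is "expressed" at a stage when
FPKM ≥ 1.  In order: one silent copy ⇒
`specialization_or_nonfunctionalization` (true neofunctionalization is
indistinguishable without an outgroup, hence the merged label); disjoint
expressed-stage sets ⇒ `subfunctionalization`; Pearson r ≥ 0.8 with both
copies expressed in ≥ half the stages ⇒ `dosage_balance` (two flat
profiles count as perfectly parallel although r is undefined); otherwise
`unclassified`.

2^−ΔΔCt relative expression: ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt subtracts the calibrator's ΔCt, fold = 2^−ΔΔCt; the calibrator fold
is exactly 1 and folds are invariant to per-sample Ct shifts.

## Synthetic world

`simulate_genome` builds a 6-chromosome × 40-slot genome (15 kb gene
pitch).  Twenty named CYP families spanning all ten clans contribute 42
P450 genes; the remaining 198 genes are decoys rejection-sampled to carry
none of the four signature regions.  Planted events:

* an 8-gene duplicated segment (chr1 ranks 5–12 ↔ chr2 ranks 8–15):
  8 WGD pairs and the genome's only two clusters;
* 4 tandem pairs (adjacent ranks), 4 proximal pairs (2 intervening);
* 2 transposed copies whose ancestral loci sit inside the duplicated
  segment (4 TRD pairs, two per host family);
* 4 dispersed pairs on different chromosomes far from everything.

Family members diverge from motif-bearing founders through
`evolve_cds`: Poisson(ks·S) synonymous and Poisson(ω·ks·N) nonsynonymous
single-base events applied in random order, never creating stops, with
nonsynonymous events barred from motif codons so planted signatures
survive.  Member divergences are 0.10 (WGD), 0.03 (tandem/proximal),
0.25 (transposed) and 0.15 (dispersed) substitutions per synonymous site
at ω = 0.2, so pair-level Ks lands near 0.2 / 0.06 / 0.35 / 0.3
respectively — WGD pairs inside the recent-WGD window, transposed pairs
older than WGD pairs, local duplicates youngest, mirroring the rank
ordering such surveys report.  Realised event counts are recorded as the
pair's true Ks/ω.  Substitution-only divergence (no indels) keeps
identity ladders tight; `mutate_protein_to_identity` provides exact-count
substitution for nomenclature-tier tests.

`simulate_expression` draws five stages (15–145 DAF) × three replicates.
Counts are Poisson around FPKM-implied means (library size 2×10⁷);
`poisson=False` writes exact rounded means for noise-free oracles.
Planted patterns: complementary high/off profiles (subfunctionalization,
4 pairs), parallel rising profiles (dosage balance, 4 pairs), one silent
copy (specialization, 3 pairs), five driver genes with a shared rising
profile, and smooth lognormal random-walk profiles for everything else.
The metabolite series is `scale × FPKM(driver) + N(0, σ)` with σ = 0.35 ×
sd(signal) — calibrated once so per-driver detection power at n = 5
stages is ≈ 0.9, then frozen.  The component-sum series is 0.6 × the
total with its own noise.

What the generator does **not** emulate — so a green test does not
establish robustness to it: indels and alignment ambiguity in family
divergence; overdispersed (negative-binomial) counts; intergenic
sequence, repeats and transposons; multi-isoform genes; shared ancestry
across multiple genomes; saturation-range divergences (Ks ≫ 1).

## Numerical choices

* One integer seed per generator call drives a single numpy Generator;
  fixed seed ⇒ byte-identical files.
* Alignment DP uses 64-bit integer scores (no float ties); traceback
  tie-break and best-reference/chain tie-breaks are documented above.
* pI bisection runs 60 iterations (≈ 1e−17 pH), far past the 0.01-pH
  requirement.
* Degenerate inputs raise early with the offending gene/position named:
  empty sequences, CDS/protein length or translation mismatches, missing
  gene ranks, constant vectors, missing reference Ct.

## Known limitations

* NG86 underestimates distances at high divergence; saturated pairs are
  flagged, not rescued by a parametric model.
* The TRD rule without outgroups conflates transposed copies with any
  pair touching a collinear block on one side.
* Cluster calls depend on the declared gap rule; alternative rules can
  merge or split clusters near the limits.
* The screen's internal similarity route is identity-based and will not
  reproduce E-value-based external searches exactly; ingest the external
  tables when available.
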