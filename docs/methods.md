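# Methods

This note documents the models, conventions and numerical choices behind
`endotag`, including the points where the design was genuinely open and the
package fixed one convention.

## Coordinates

Internally everything is 0-based, half-open, on the plus strand. Insertion
points are *inter-base*: offset k names the boundary between plus-strand
bases k−1 and k, which removes every off-by-one ambiguity when inserting
between codons. GFF3 input (1-based inclusive) is converted at the parser
boundary; user-facing tables are 1-based inclusive; BED output is 0-based
half-open. CDS segments include the stop codon, so the protein length is
CDS/3 − 1 — this matches the common GFF3 dialects in which CDS features run
through the stop. Reports also carry the 1-based position of the nucleotide
immediately 5′ of the insertion boundary in transcript orientation, the
coordinate style genome engineers typically quote.

If a codon boundary coincides with an exon–intron junction, the insertion
coordinate is placed on the exon side adjacent in transcript orientation
(the last exonic base of the upstream codon): insertions must be exonic, and
the alternative (intron side) would put the tag inside an intron. Gene
models whose spliced CDS lacks an ATG start, a stop, or a length divisible
by 3 produce per-gene warnings (`NO_ATG`, `NO_STOP`,
`NONCANONICAL_CDS_LENGTH`), never a crash: real annotation sets always
contain a few such genes and a batch run must survive them.

## Mature-protein boundaries

The N-terminal boundary is the maximum over all annotated N-terminal
processing events (initiator-Met removal → 2; signal or transit peptide end
+ 1; propeptides chained off the running boundary; chain start), the
C-terminal boundary the symmetric minimum (protein length, chain end,
C-terminal propeptide start − 1). Propeptide chaining iterates to a fixed
point so stacked propeptides behave correctly.

"Five residues proximal to a terminal lipidation site" is implemented as:
if a lipidation site of the matching terminal class lies within 5 residues
of the boundary, the boundary moves so that exactly five native residues
separate the insertion point from the lipidated residue (N: boundary =
site + 6; C: boundary = site − 6) and `LIPIDATION_ADJUSTED` is flagged. The
distance is stated in the literature; the arithmetic convention is fixed
here and used consistently by the generator and the pipeline.

With no processing annotation at all, the N-terminal site stays before
residue 1 and the spec carries a `NO_PROCESSING_INFO` note — the choice is
flagged rather than silently guessed.

Motif warnings use canonical textbook patterns, fixed here because "simple
motif search" admits many regexes: PTS1 `[SAC][KRH][LM]$`; PTS2
`[RK][LVIQ]..[LVIHQ][SGAK]` within residues 1–40; KDEL `[KHRQ][DE]EL$`;
di-lysine K at −3 with K at −4 or −5; CAAX `C[aliphatic][aliphatic]X$` with
aliphatic = AVILMF. Motif hits never move a coordinate.

## Guide selection

Window ±50 nt around the insertion point, truncated (and flagged) at contig
ends, with one base of padding fetched for the PAM-context check. GC bounds
are inclusive and computed on the 20-nt protospacer only; homopolymer and
poly-T checks likewise cover the protospacer only, since only the
protospacer is transcribed into the sgRNA. A base that cannot be verified
(window at a contig end) fails the PAM-context check conservatively. N bases
disqualify overlapping candidates.

Ranking is (off-target count ↑, cut-to-insertion distance ↑, plus strand
before minus, smaller genomic start). The last two tie-breaks are arbitrary
but deterministic: identical inputs give byte-identical selections. The best
in-vivo guide is always reported; an in-vitro-only guide is added only when
its cut is strictly closer.

Off-target counting uses ungapped Hamming distance to every NGG-adjacent
20-mer in the genome, default ≤ 3 mismatches — a standard desk-scale
criterion, configurable. Sites are 2-bit packed into uint64; a query is one
XOR plus a per-2-bit popcount over the whole index, and a naive
position-by-position scan serves as the test oracle. Bulged off-targets and
activity scores (Doench/CFD) are out of scope. Primer specificity is
operationalized as full-length exact occurrences == 1 across both strands.

## Silent mutations and primers

Mutable footprint: the two PAM G bases plus the 3′-most eight protospacer
bases (the seed), processed PAM-first then seed PAM-proximal-first, since
changes there destroy recognition most effectively. Codons overlapping the
footprint are replaced by the synonymous codon changing the most footprint
bases (hard cap: never exceed 5 total changes; stop once 4 are reached);
"4–5 mutations" counts nucleotides, not codons. Footprint bases in introns
or UTRs are changed freely by a fixed transversion map. No change is placed
within 3 nt of an exonic splice boundary or 6 nt on the intron side, to
avoid disrupting splicing. When the footprint offers fewer than four
changes (Met/Trp codons), the plan carries
`INSUFFICIENT_SILENT_MUTATIONS` rather than inventing non-synonymous edits.
Every emitted plan is re-checked for synonymy at construction time.

Anchored primers P2 (upstream) and P3 (downstream) point away from the
junction, so the 15-unmodified-3′-base rule binds exactly when mutations sit
far from the junction; the primer length is the shortest L in [30, 35] with
max(distance) ≤ L − 15. When that is impossible (max distance > 20), the
split design is used: the inner primer (P2B/P3B) is 35 nt anchored at the
junction carrying only mutations within its allowance, and the auxiliary
primer (P2A/P3A) starts 20 nt inside the inner primer's distal end and
extends to cover the farthest mutation plus 15 clean 3′ bases (minimum
30 nt; longer than 35 nt is permitted with `AUX_PRIMER_LONG`, because a
35-nt cap cannot simultaneously hold the stated 20-nt overlap and mutations
~50 nt out).

Melting temperatures use the Allawi–SantaLucia nearest-neighbor parameters
under fixed conditions (25 nM each strand, 50 mM monovalent cation,
entropy salt correction 0.368·(N−1)·ln[Mon⁺]); the implementation is
cross-checked against Biopython's `Tm_NN` to float precision, and a
prefix-sum variant makes scoring every candidate window cheap. Outer
primers (18–27 nt, GC 30–70%) must match their anchored partner within
3 °C; candidates are ranked by |ΔTm|, then amplicon length closest to
500 bp, then leftmost start. The search window targets 500–1000 bp arms and
expands in 500-nt steps to 10 kb; specificity is checked on the best
candidates first, and if none is unique the best scorer is returned with
`NONSPECIFIC_PRIMER` ("when possible" semantics). Genotyping primers are
searched in fixed 500-nt margins outside the arms (never inward), aimed at
60 °C and Tm-matched to each other; their amplicon strictly contains both
arms, enabling a nested two-step workflow.

## Survey statistics

Deduplication groups alleles by (gene, sorted tags, sorted positions) and
keeps the earliest year, tie-broken by lexicographic allele designation —
idempotent by construction. Source merging joins on allele designation when
present, else on the dedup key; a designation pointing at different genes in
the two sources warns and keeps the literature assignment.

Percentages round half away from zero to one decimal, which reproduces every
self-consistent printed fraction→percentage pair; tag-*position*
distributions are over alleles (an allele tagged at two positions counts
once under "multiple") and tag-*type* distributions are normalised over tag
instances so each reported distribution sums to 100%. Per-allele tag
fractions (which overlap and need not sum to 100%) are exposed separately.

Enrichment uses the 2×2 table [[t, n−t], [T−t, (N−n)−(T−t)]] (category rows,
tagged columns), the cross-product odds ratio, a two-sided Fisher exact
test and Benjamini–Hochberg q-values; log₂(OR) is reported capped at ±7 in
place of ±∞ so fully tagged/untagged categories remain plottable, and no
continuity correction is applied (capping handles the infinities). The BH
step-up is implemented directly from its formula and cross-checked against
statsmodels in the tests. Two sensible backgrounds exist — genes with ≥ 1
annotation for ontology enrichment, all protein-coding genes for disease
enrichment — and the API takes the background explicitly.

Accrual uses OLS on cumulative unique genes per year (a gene counts once,
in its earliest year); the discovery curve fits
G(n) = G_max·(1 − exp(−n/τ)) by Levenberg–Marquardt with positivity bounds,
and the effort to reach fraction f of the asymptote is −τ·ln(1−f).

## Synthetic fixtures

The genome generator writes clean ORFs (ATG…stop, no internal stops) split
into 1–5 exons at arbitrary nucleotide positions (deliberately not codon
boundaries, to exercise junction handling), GT…AG introns of 48–200 nt,
both strands with equal probability, ~36% GC (nematode-like), and ~2.4 kb
intergenic spacing so homology-arm searches have room. Feature scenarios
(init-Met removal, signal ± propeptide, transit, C-propeptide, chain,
terminal lipidation) are drawn with fixed probabilities, and the truth
table — expected boundary residues and genomic coordinates — is computed
during construction from the generator's own base-by-base bookkeeping,
independently of the coordinate-walking code under test.

The inventory generator allocates the published mixture exactly (largest-
remainder apportionment): alleles per gene 63.1/19.7/8.3/8.9%, positions
C 62.9 / N 33.7 / internal 2.9 / multiple 0.5%, tags GFP 44.0 / mNeonGreen
17.0 / FLAG 30.1% with the remainder split across other common tags, linear
accrual of ~203 newly tagged genes per year from 2020 with a ramp before,
and a discovery curve with G_max = 1700 and τ = 2424/ln 10 ≈ 1052.6 (the
effort at which 90% coverage is reached is then ~2424 papers). Multi-allele
genes receive distinct (tag, position) combinations so deduplication removes
only deliberately injected duplicates. It is a synthetic stand-in with known
truth, not a copy of any real inventory.

What passing tests show — and what they do not: the fixtures have uniform
codon usage, no repeats beyond chance, no alternative isoforms, no
sequencing N's except where planted, and clean annotations. Passing the
sweeps therefore demonstrates correctness of the coordinate arithmetic,
filters and constructions, not robustness to messy real annotation (phase
errors, pseudo-genes, micro-exons), which the warning pathways only
partially cover.

## Problem sizes and determinism

The test suite runs the oracle sweeps at 500 random windows (guide
enumeration), a 100-kb genome across mismatch levels 0–4 (off-targets), a
1,000-gene genome (filter soundness, synonymy/15-base rule, coordinate
truth), exhaustive 2×2 tables to N = 30 plus a seeded sample to N = 200
(Fisher), sizes chosen so the whole suite completes in well under a minute
of compute per sweep while covering both strands and all feature
combinations. All randomness flows through seeded `numpy` generators;
identical seeds give byte-identical fixture files and design tables.
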