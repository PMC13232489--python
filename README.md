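# endotag

CRISPR knock-in design and tagged-allele survey statistics for *C. elegans*-style
genomes.

Endogenous protein tagging — inserting a fluorophore, epitope or degron
in-frame at a gene's native locus — is how modern worm biology reads out
protein expression, localization and dynamics without overexpression
artifacts. Designing one knock-in by hand means choosing an insertion point
that survives protein maturation, picking an SpCas9 guide whose cut sits near
it, and building homology-arm and genotyping primers that the nuclease cannot
re-cut. `endotag` automates all of it against any FASTA + GFF3 gene set, and
also provides the statistics used to survey a community's tagged-allele
inventory: curation/deduplication rules, summary distributions, accrual
models and Gene Ontology / disease-category enrichment.

It is written for genome engineers planning knock-ins at scale, and for
anyone analysing which parts of a proteome have (not) been tagged.

## What it computes

**Insertion sites.** The tag must land on the *mature* polypeptide. From
UniProt-style features, the first mature residue is

    max{1; 2 if init-Met removed; signal_end+1; transit_end+1;
        propeptide_end+1 (chained); chain_start}

and the last retained residue is the symmetric minimum at the C-terminus.
Terminal lipidation sites push the boundary so that exactly five native
residues separate tag and lipidated residue. Sorting motifs (PTS1/PTS2, KDEL,
di-lysine, CAAX) are reported as warning flags only. The residue boundary is
converted, exon-aware and strand-aware, to an inter-base genomic coordinate
(the nucleotide immediately 5′ of the codon boundary in transcript
orientation).

**Guides.** Both strands of a ±50 bp window are scanned for 20-nt
protospacers with an NGG PAM; the blunt cut is 3 bp 5′ of the PAM (between
protospacer positions 17|18). Filters: GC ∈ [25, 80]%, no homopolymer ≥ 7 nt,
PAM ≠ GGG, next non-guide base ≠ G; a TTTT run restricts a guide to in-vitro
transcription. Candidates are ranked by genome-wide off-target count
(Hamming distance ≤ 3 to any NGG site, counted with a 2-bit-packed vectorised
index), then by cut-to-insertion distance.

**Primers.** Primers 2/3 anchor the homology arms at the junction (30–35 nt,
pointing away from it) and carry 4–5 silent mutations placed in the codons
under the guide seed and PAM so the repaired allele is immune to re-cutting;
when a mutation would fall within the 15 3′-terminal bases, an overlapping
2-primer design (2A/2B, 3A/3B) is used. Primers 1/4 are picked by
nearest-neighbor melting temperature (Allawi–SantaLucia parameters) to give
500–1000 bp arms, expanding to 10 kb if needed, and must occur exactly once
in the genome. A genotyping pair flanks the entire edited region.

**Survey statistics.** One representative allele per (gene, tags, positions)
with the earliest publication kept; alleles-per-gene / tag-type /
tag-position distributions; linear tagging-rate fits; an exponential-
saturation discovery curve G(n) = G_max·(1 − e^(−n/τ)) with effort-to-
fraction n(f) = −τ·ln(1−f); and per-category enrichment via the 2×2 odds
ratio, two-sided Fisher exact test and Benjamini–Hochberg FDR, with
log₂(OR) capped at ±7 in place of infinite values.

A deterministic synthetic-fixture generator (`endotag.fixtures`) emulates all
inputs — genome, gene models, feature table, allele inventory — with
generator-side ground truth, so the whole pipeline is testable offline.

## Worked example

```bash
endotag simulate --seed 7 --genes 3 --out demo/fix
endotag design --genome demo/fix/genome.fa --gff demo/fix/genes.gff3 \
               --features demo/fix/protein_features.tsv --out demo/design
```

prints `designed 6 target sites (0 gene-level warnings, see design.log)` and
writes `design.tsv`:

```
gene_id  terminus  boundary_residue  insertion_coord_1based  guide_sequence        guide_pam  guide_class  guide_offtargets
sg-1     N         19                1654                    CGCTCGGTACTGGTTGAGGT  AGG        in_vivo      0
sg-1     C         186               2158                    GGATACAAAAGGAGTGTGAT  TGG        in_vivo      0
sg-2     N         2                 4618                    TTGAACACATGAGCTTGTAC  AGG        in_vivo      0
...
```

Gene `sg-1` carries a transit peptide ending at residue 12 and an N-terminal
lipidation site at residue 13, so its N-terminal tag goes before residue 19 —
past the cleaved segment and five residues clear of the lipidated residue,
not after the start codon — at the 1-based coordinate of the nucleotide
immediately 5′ of that codon boundary (1654). Its C-terminal propeptide
(187–204) likewise pulls the C-terminal site up to residue 186.
Each selected guide passed every composition filter and has zero off-target
sites within three mismatches. `primers.tsv` holds the matching primer set,
e.g. for the sg-1 N terminus a P2/P3 pair at Tm ≈ 66 °C carrying the silent
mutations, Tm-matched outer primers P1/P4 giving 500–1000 bp arms, and a
genotyping pair flanking the whole edited region.

The same pipeline is available as a library (`endotag.pipeline.design_batch`),
and `endotag survey` / `endotag enrich` run the inventory statistics.

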