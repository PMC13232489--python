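"""Genome and gene-model containers with strand-aware coordinate conversion.

Internal convention: all coordinates are 0-based, half-open, on the plus
strand. Insertion points are *inter-base*: an offset ``k`` names the boundary
between plus-strand bases ``k-1`` and ``k``. User-facing reports convert to
1-based inclusive at the output boundary; GFF3 input (1-based inclusive) is
converted at the parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class InterbaseCoord:
    """A boundary between two adjacent plus-strand bases.

    ``offset`` k denotes the boundary between bases k-1 and k (0-based),
    so 0 is the boundary before the first base and ``len`` the boundary
    after the last.
    """

    chromosome: str
    offset: int


class GenomeAssembly:
    """Named chromosome sequences over the {A,C,G,T,N} alphabet."""

    def __init__(self, chromosomes: dict[str, str], assembly_name: str | None = None):
        if not chromosomes:
            raise ValueError("assembly must contain at least one chromosome")
        clean: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be nonempty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.chromosomes = clean
        self.assembly_name = assembly_name

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def length(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.chromosomes.items()}

    def sequence(self, chromosome: str, start: int, end: int) -> str:
        """Plus-strand slice [start, end), bounds-checked."""
        seq = self.chromosomes[chromosome]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"slice [{start}, {end}) out of bounds for {chromosome} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


def load_genome(fasta_path, assembly_name: str | None = None) -> GenomeAssembly:
    """Read a (wrapped or unwrapped) multi-record FASTA into a GenomeAssembly."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in chroms:
            raise ValueError(f"duplicate FASTA record name: {record.id!r}")
        chroms[record.id] = str(record.seq)
    return GenomeAssembly(chroms, assembly_name=assembly_name)


@dataclass
class TranscriptModel:
    """Canonical-transcript CDS structure.

    ``cds_segments`` are 0-based half-open plus-strand intervals stored in
    ascending order regardless of strand; the stop codon is included, so the
    protein length is CDS/3 - 1.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]]
    is_canonical: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"{self.transcript_id}: empty CDS segment list")
        segs = sorted(self.cds_segments)
        for (s0, e0), (s1, e1) in zip(segs, segs[1:]):
            if e0 > s1:
                raise ValueError(f"{self.transcript_id}: overlapping CDS segments")
        for s, e in segs:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty/inverted segment {(s, e)}")
        self.cds_segments = segs
        if self.cds_length % 3 != 0:
            self._warn("NONCANONICAL_CDS_LENGTH")

    def _warn(self, flag: str) -> None:
        if flag not in self.warnings:
            self.warnings.append(flag)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int:
        """Residues in the encoded protein (stop codon excluded)."""
        return self.cds_length // 3 - 1

    def check_orf(self, genome: GenomeAssembly) -> list[str]:
        """Warn (never crash) if the spliced CDS lacks an ATG start or stop end."""
        cds = spliced_cds(self, genome)
        if not cds.startswith("ATG"):
            self._warn("NO_ATG")
        if len(cds) % 3 == 0 and cds[-3:] not in ("TAA", "TAG", "TGA"):
            self._warn("NO_STOP")
        return self.warnings


def spliced_cds(transcript: TranscriptModel, genome: GenomeAssembly) -> str:
    """Spliced CDS in transcript orientation (reverse-complemented on minus)."""
    parts = [
        genome.sequence(transcript.chromosome, s, e) for s, e in transcript.cds_segments
    ]
    seq = "".join(parts)
    return revcomp(seq) if transcript.strand == "-" else seq


def protein_sequence(transcript: TranscriptModel, genome: GenomeAssembly) -> str:
    """Translation of the spliced CDS, trailing stop removed if present."""
    cds = spliced_cds(transcript, genome)
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate())
    return aa[:-1] if aa.endswith("*") else aa


def _cds_offset_to_interbase(transcript: TranscriptModel, cds_offset: int) -> int:
    """Map a transcript-orientation CDS offset to a plus-strand inter-base offset.

    When the boundary coincides with an exon-intron junction, the coordinate
    is placed on the exon side adjacent in transcript orientation (the last
    exonic base of the upstream codon), since insertions must be exonic.
    """
    remaining = cds_offset
    if transcript.strand == "+":
        for s, e in transcript.cds_segments:
            if remaining <= e - s:
                return s + remaining
            remaining -= e - s
    else:
        for s, e in reversed(transcript.cds_segments):
            if remaining <= e - s:
                return e - remaining
            remaining -= e - s
    raise ValueError(
        f"CDS offset {cds_offset} outside CDS of length {transcript.cds_length}"
    )


def aa_boundary_to_genomic(
    transcript: TranscriptModel, residue_index: int, side: str
) -> tuple[InterbaseCoord, int]:
    """Genomic coordinate of a codon boundary.

    ``side='before'`` names the boundary 5' of codon ``residue_index``,
    ``side='after'`` the boundary 3' of it (both in transcript orientation).
    Returns the inter-base coordinate together with the 1-based plus-strand
    position of the nucleotide immediately 5' of the boundary in transcript
    orientation (the coordinate style used in design reports).
    """
    if side not in ("before", "after"):
        raise ValueError(f"side must be 'before' or 'after', got {side!r}")
    n_res = transcript.protein_length
    if not (1 <= residue_index <= n_res + 1):
        raise ValueError(
            f"residue index {residue_index} outside 1..{n_res + 1} "
            f"for {transcript.transcript_id}"
        )
    cds_offset = 3 * (residue_index - 1) if side == "before" else 3 * residue_index
    if cds_offset > transcript.cds_length:
        raise ValueError("codon boundary lands outside the CDS")
    off = _cds_offset_to_interbase(transcript, cds_offset)
    if transcript.strand == "+":
        five_prime_1based = off  # base [off-1, off) is immediately 5'
    else:
        five_prime_1based = off + 1  # base [off, off+1) is immediately 5'
    return InterbaseCoord(transcript.chromosome, off), five_prime_1based


def _check_phase(segments: list[tuple[int, int, str]], strand: str, tid: str) -> bool:
    """True iff the recorded GFF3 CDS phases are mutually consistent."""
    ordered = sorted(segments, key=lambda t: t[0], reverse=(strand == "-"))
    running = 0
    for s, e, phase in ordered:
        if phase not in (".", ""):
            if (3 - running % 3) % 3 != int(phase):
                return False
        running += e - s
    return True


def load_transcripts(
    gff3_path,
    canonical_selector="canonical=1",
    genome: GenomeAssembly | None = None,
) -> list[TranscriptModel]:
    """Parse gene/mRNA/CDS features from GFF3 and keep one canonical transcript
    per gene.

    ``canonical_selector`` is either an ``"attribute=value"`` tag carried on the
    chosen mRNA (default ``"canonical=1"``) or a mapping gene_id -> transcript_id.
    Raises for genes with no CDS on any transcript or a missing canonical
    transcript; ORF irregularities only warn.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    attr_tag = attr_value = None
    explicit: dict[str, str] | None = None
    if isinstance(canonical_selector, str):
        attr_tag, _, attr_value = canonical_selector.partition("=")
    else:
        explicit = dict(canonical_selector)

    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ValueError(f"gene {gene.id}: no mRNA features")
        chosen = None
        if explicit is not None:
            want = explicit.get(gene.id)
            chosen = next((m for m in mrnas if m.id == want), None)
        else:
            for m in mrnas:
                if attr_value in m.attributes.get(attr_tag, []):
                    chosen = m
                    break
        if chosen is None:
            raise ValueError(f"gene {gene.id}: canonical transcript not found")
        cds = [
            (f.start - 1, f.end, f.frame)
            for f in db.children(chosen, featuretype="CDS")
        ]
        if not cds:
            raise ValueError(f"gene {gene.id}: canonical transcript has no CDS")
        model = TranscriptModel(
            transcript_id=chosen.id,
            gene_id=gene.id,
            chromosome=chosen.seqid,
            strand=chosen.strand,
            cds_segments=[(s, e) for s, e, _ in cds],
        )
        if not _check_phase(cds, chosen.strand, chosen.id):
            model._warn("INCONSISTENT_PHASE")
        if genome is not None:
            model.check_orf(genome)
        models.append(model)
    return models


def write_bed6(path, records) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6
    (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
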