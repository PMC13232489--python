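"""Mature-protein boundary inference and insertion-site specification.

An N-terminal tag placed before a cleaved signal/transit/propeptide would be
removed with it during maturation, so the N-terminal insertion boundary sits
immediately downstream of every predicted N-terminal processing event, and the
C-terminal boundary immediately upstream of residues expected to be removed.
Terminal lipidation sites push the boundary five residues away. Sorting-motif
hits (PTS1/PTS2, KDEL, di-lysine, CAAX) are low-confidence and only ever
produce warning flags; they never move a coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .genome import (
    GenomeAssembly,
    InterbaseCoord,
    TranscriptModel,
    aa_boundary_to_genomic,
    protein_sequence,
)

#: the full set of warning flags an InsertionSpec may carry
WARNING_FLAGS = frozenset(
    {
        "PTS1",
        "PTS2",
        "KDEL",
        "DILYS",
        "CAAX",
        "NO_ATG",
        "NONCANONICAL_CDS_LENGTH",
        "LIPIDATION_ADJUSTED",
    }
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Warning-only motif patterns (canonical textbook definitions; the exact
# regexes are a documented package choice).
_PTS1_RE = re.compile(r"[SAC][KRH][LM]$")
_PTS2_RE = re.compile(r"[RK][LVIQ]..[LVIHQ][SGAK]")
_KDEL_RE = re.compile(r"[KHRQ][DE]EL$")
_CAAX_RE = re.compile(r"C[AVILMF][AVILMF].$")


@dataclass
class ProteinFeatureSet:
    """UniProt-style maturation features for one protein."""

    uniprot_id: str
    protein_length: int
    init_met_removed: bool = False
    signal_peptide: tuple[int, int] | None = None  # [1, s]
    transit_peptide: tuple[int, int] | None = None  # [1, t]
    propeptides: list[tuple[int, int]] = field(default_factory=list)
    chain: tuple[int, int] | None = None
    lipidation_sites: list[tuple[int, str]] = field(default_factory=list)  # (pos, N/C/internal)

    def __post_init__(self):
        if self.protein_length < 1:
            raise ValueError("protein_length must be positive")
        for name in ("signal_peptide", "transit_peptide"):
            iv = getattr(self, name)
            if iv is not None:
                a, b = iv
                if a != 1:
                    raise ValueError(f"{name} must start at residue 1, got {iv}")
                self._check_interval(iv, name)
        for iv in self.propeptides:
            self._check_interval(iv, "propeptide")
        if self.chain is not None:
            self._check_interval(self.chain, "chain")
        for pos, cls in self.lipidation_sites:
            if not (1 <= pos <= self.protein_length):
                raise ValueError(f"lipidation site {pos} outside protein")
            if cls not in ("N", "C", "internal"):
                raise ValueError(f"unknown lipidation terminal class {cls!r}")

    def _check_interval(self, iv: tuple[int, int], name: str) -> None:
        a, b = iv
        if not (1 <= a <= b <= self.protein_length):
            raise ValueError(f"{name} interval {iv} outside [1, {self.protein_length}]")

    @property
    def has_n_processing(self) -> bool:
        return bool(
            self.init_met_removed
            or self.signal_peptide
            or self.transit_peptide
            or self.propeptides
            or self.chain
            or any(cls == "N" for _, cls in self.lipidation_sites)
        )


@dataclass
class InsertionSpec:
    """A terminus-specific insertion point in both residue and genomic space."""

    gene_id: str
    terminus: str  # 'N' or 'C'
    boundary_residue: int  # first mature (N) or last retained (C) residue
    genomic_point: InterbaseCoord
    five_prime_coord: int  # 1-based nt immediately 5' of boundary, transcript sense
    warning_flags: set[str] = field(default_factory=set)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = self.warning_flags - WARNING_FLAGS
        if bad:
            raise ValueError(f"unknown warning flags: {sorted(bad)}")


def infer_mature_start(features: ProteinFeatureSet) -> int:
    """First mature residue: downstream of all N-terminal processing events."""
    b = 1
    if features.init_met_removed:
        b = 2
    if features.signal_peptide:
        b = max(b, features.signal_peptide[1] + 1)
    if features.transit_peptide:
        b = max(b, features.transit_peptide[1] + 1)
    # propeptides chain off whatever boundary the earlier events produced
    changed = True
    while changed:
        changed = False
        for a, e in features.propeptides:
            if a <= b and e + 1 > b:
                b = e + 1
                changed = True
    if features.chain:
        b = max(b, features.chain[0])
    if b > features.protein_length:
        raise ValueError(
            f"mature start {b} beyond protein length {features.protein_length}"
        )
    return b


def infer_mature_end(features: ProteinFeatureSet) -> int:
    """Last retained residue: upstream of residues expected to be removed."""
    e = features.protein_length
    if features.chain:
        e = min(e, features.chain[1])
    changed = True
    while changed:
        changed = False
        for a, b in features.propeptides:
            if b >= e and a - 1 < e and a > 1:
                e = a - 1
                changed = True
    if e < 1:
        raise ValueError("no residues retained at the C-terminus")
    return e


def apply_lipidation_offset(
    boundary: int, lipidation_sites: list[tuple[int, str]], terminus: str
) -> tuple[int, bool]:
    """Move a boundary so exactly five native residues separate the insertion
    point from a terminal lipidation site; returns (boundary, adjusted)."""
    adjusted = False
    for pos, cls in lipidation_sites:
        if cls != terminus:
            continue
        if abs(pos - boundary) <= 5:
            boundary = pos + 6 if terminus == "N" else pos - 6
            adjusted = True
    return boundary, adjusted


def scan_sorting_motifs(protein_seq: str) -> set[str]:
    """Warning-only sorting/modification motif flags for a protein sequence."""
    flags: set[str] = set()
    seq = protein_seq.upper()
    if _PTS1_RE.search(seq):
        flags.add("PTS1")
    if _PTS2_RE.search(seq[:40]):
        flags.add("PTS2")
    if _KDEL_RE.search(seq):
        flags.add("KDEL")
    if len(seq) >= 5 and seq[-3] == "K" and "K" in (seq[-4], seq[-5]):
        flags.add("DILYS")
    if _CAAX_RE.search(seq):
        flags.add("CAAX")
    return flags


def make_insertion_specs(
    transcript: TranscriptModel,
    features: ProteinFeatureSet,
    genome: GenomeAssembly,
    scan_motifs: bool = True,
) -> tuple[InsertionSpec, InsertionSpec]:
    """Emit the N- and C-terminal insertion specifications for one gene."""
    if features.protein_length != transcript.protein_length:
        raise ValueError(
            f"{transcript.gene_id}: feature table protein length "
            f"{features.protein_length} != CDS-implied {transcript.protein_length}"
        )
    protein = protein_sequence(transcript, genome)
    motif_flags = scan_sorting_motifs(protein) if scan_motifs else set()
    structural = {w for w in transcript.warnings if w in WARNING_FLAGS}

    n_boundary = infer_mature_start(features)
    n_boundary, n_adj = apply_lipidation_offset(
        n_boundary, features.lipidation_sites, "N"
    )
    c_boundary = infer_mature_end(features)
    c_boundary, c_adj = apply_lipidation_offset(
        c_boundary, features.lipidation_sites, "C"
    )
    if not (1 <= n_boundary <= features.protein_length):
        raise ValueError(f"{transcript.gene_id}: N boundary {n_boundary} outside protein")
    if not (1 <= c_boundary <= features.protein_length):
        raise ValueError(f"{transcript.gene_id}: C boundary {c_boundary} outside protein")
    if n_boundary > c_boundary:
        raise ValueError(
            f"{transcript.gene_id}: mature start {n_boundary} beyond mature end {c_boundary}"
        )

    # N tag goes before the first mature residue; C tag after the last
    # retained residue (immediately 5' of the stop codon when unprocessed).
    n_point, n_paper = aa_boundary_to_genomic(transcript, n_boundary, "before")
    c_point, c_paper = aa_boundary_to_genomic(transcript, c_boundary, "after")

    n_spec = InsertionSpec(
        gene_id=transcript.gene_id,
        terminus="N",
        boundary_residue=n_boundary,
        genomic_point=n_point,
        five_prime_coord=n_paper,
        warning_flags=motif_flags | structural | ({"LIPIDATION_ADJUSTED"} if n_adj else set()),
    )
    if not features.has_n_processing:
        n_spec.notes.append("NO_PROCESSING_INFO")
    c_spec = InsertionSpec(
        gene_id=transcript.gene_id,
        terminus="C",
        boundary_residue=c_boundary,
        genomic_point=c_point,
        five_prime_coord=c_paper,
        warning_flags=motif_flags | structural | ({"LIPIDATION_ADJUSTED"} if c_adj else set()),
    )
    return n_spec, c_spec


def _parse_interval(text) -> tuple[int, int] | None:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return None
    a, _, b = str(text).partition("-")
    return (int(a), int(b))


def read_feature_table(path) -> dict[str, ProteinFeatureSet]:
    """Read the protein-processing feature TSV into per-gene feature sets.

    Columns: uniprot_id, gene_id, length, init_met_removed (0/1), signal_end,
    transit_end, propeptides ('a-b;c-d'), chain ('a-b'),
    lipidation ('pos:class;...').
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, ProteinFeatureSet] = {}
    for row in df.itertuples(index=False):
        length = int(row.length)
        propeptides = [
            _parse_interval(p) for p in str(row.propeptides).split(";") if p
        ]
        lipidation = []
        for item in str(row.lipidation).split(";"):
            if item:
                pos, _, cls = item.partition(":")
                lipidation.append((int(pos), cls))
        out[row.gene_id] = ProteinFeatureSet(
            uniprot_id=row.uniprot_id,
            protein_length=length,
            init_met_removed=str(row.init_met_removed) == "1",
            signal_peptide=(1, int(row.signal_end)) if row.signal_end else None,
            transit_peptide=(1, int(row.transit_end)) if row.transit_end else None,
            propeptides=propeptides,
            chain=_parse_interval(row.chain),
            lipidation_sites=lipidation,
        )
    return out
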