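"""Homology-arm and genotyping primer design with silent-mutation planning.

The repair template must not be re-cut by the selected guide, so 4-5 silent
(synonymous) nucleotide changes are placed in the codons under the guide's
3'-most eight protospacer bases (the seed) and the PAM GG. Primers 2 and 3
anchor the two homology arms at the insertion junction (30-35 nt, pointing
away from the junction) and carry those mutations; when a mutation would fall
inside the 15 3'-terminal bases of an anchored primer, an overlapping
two-primer design (2A/2B or 3A/3B) is used instead. Outer primers 1 and 4 are
picked by nearest-neighbor melting temperature to give 500-1000 bp arms
(expanded up to 10 kb when necessary), and a genotyping pair flanks the whole
edited region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genome import GenomeAssembly, InterbaseCoord, TranscriptModel, revcomp
from .guides import GuideCandidate
from .offtargets import exact_occurrences

# ---------------------------------------------------------------------------
# Nearest-neighbor melting temperature (Allawi & SantaLucia 1997 parameters;
# dH kcal/mol, dS cal/(mol*K)). Conditions are fixed and documented: 25 nM
# each strand, 50 mM monovalent salt, entropy-based salt correction
# 0.368*(N-1)*ln[Mon+].

_NN_TABLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = (0.0, 0.0)
_INIT_AT = (2.3, 4.1)  # per terminal A/T
_INIT_GC = (0.1, -2.8)  # per terminal G/C
_SYM = (0.0, -1.4)
_R = 1.987  # cal/(mol*K)
_DNAC1 = 25.0  # nM
_DNAC2 = 25.0
_MONOVALENT = 50.0  # mM


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm in degrees C under the module's fixed conditions."""
    seq = seq.upper()
    if len(seq) < 2 or set(seq) - set("ACGT"):
        return float("nan")
    dh, ds = _INIT
    for end in (seq[0], seq[-1]):
        term = _INIT_AT if end in "AT" else _INIT_GC
        dh += term[0]
        ds += term[1]
    for i in range(len(seq) - 1):
        h, s = _NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    if seq == revcomp(seq):
        dh += _SYM[0]
        ds += _SYM[1]
    ds += 0.368 * (len(seq) - 1) * math.log(_MONOVALENT / 1000.0)
    k = (_DNAC1 - _DNAC2 / 2.0) * 1e-9
    return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


class _RegionThermo:
    """Prefix-summed NN thermodynamics over one region string, for cheap Tm
    of any substring during outer-primer search."""

    def __init__(self, region: str):
        self.region = region.upper()
        n = len(self.region)
        dh = np.zeros(max(n - 1, 0))
        ds = np.zeros(max(n - 1, 0))
        self.valid = np.array([b in "ACGT" for b in self.region], dtype=bool)
        for i in range(n - 1):
            pair = self.region[i : i + 2]
            if pair in _NN_TABLE:
                dh[i], ds[i] = _NN_TABLE[pair]
        self._cum_h = np.concatenate(([0.0], np.cumsum(dh)))
        self._cum_s = np.concatenate(([0.0], np.cumsum(ds)))
        self._cum_valid = np.concatenate(([0], np.cumsum(~self.valid)))
        gc = np.array([b in "GC" for b in self.region], dtype=np.int32)
        self._cum_gc = np.concatenate(([0], np.cumsum(gc)))

    def has_n(self, start: int, length: int) -> bool:
        return bool(self._cum_valid[start + length] - self._cum_valid[start])

    def gc_percent(self, start: int, length: int) -> float:
        return 100.0 * (self._cum_gc[start + length] - self._cum_gc[start]) / length

    def tm(self, start: int, length: int) -> float:
        """Tm of region[start:start+length]; the reverse complement has the
        same stack sum and terminal classes, so one orientation suffices."""
        if length < 2 or self.has_n(start, length):
            return float("nan")
        sub_first = self.region[start]
        sub_last = self.region[start + length - 1]
        dh = _INIT[0] + self._cum_h[start + length - 1] - self._cum_h[start]
        ds = _INIT[1] + self._cum_s[start + length - 1] - self._cum_s[start]
        for end in (sub_first, sub_last):
            term = _INIT_AT if end in "AT" else _INIT_GC
            dh += term[0]
            ds += term[1]
        sub = self.region[start : start + length]
        if sub == revcomp(sub):
            dh += _SYM[0]
            ds += _SYM[1]
        ds += 0.368 * (length - 1) * math.log(_MONOVALENT / 1000.0)
        k = (_DNAC1 - _DNAC2 / 2.0) * 1e-9
        return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# Parameters and result containers


@dataclass
class PrimerParameters:
    anchored_len_min: int = 30
    anchored_len_max: int = 35
    min_unmodified_3prime: int = 15
    overlap: int = 20  # split-design overlap between inner and auxiliary
    outer_len_min: int = 18
    outer_len_max: int = 27
    arm_min: int = 500
    arm_max: int = 1000
    arm_hard_max: int = 10_000
    expand_step: int = 500
    tm_target: float = 60.0
    tm_tolerance: float = 3.0
    outer_gc_min: float = 30.0
    outer_gc_max: float = 70.0
    geno_margin: int = 500
    max_specificity_checks: int = 50
    silent_mutation_min: int = 4
    silent_mutation_max: int = 5
    seed_length: int = 8  # 3'-most protospacer bases eligible for mutation
    exon_junction_guard: int = 3  # exon-side guard around splice junctions
    intron_junction_guard: int = 6


@dataclass
class SilentMutation:
    genomic_pos: int  # 0-based plus strand
    ref: str  # plus-strand bases
    alt: str
    residue_index: int | None  # 1-based; None for intron/UTR changes
    codon_before: str | None  # transcript sense
    codon_after: str | None


@dataclass
class SilentMutationPlan:
    mutations: list[SilentMutation] = field(default_factory=list)
    pam_disrupted: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.mutations)

    def as_position_map(self) -> dict[int, str]:
        return {m.genomic_pos: m.alt for m in self.mutations}


@dataclass
class Primer:
    name: str
    sequence: str  # 5' -> 3'
    chromosome: str
    span: tuple[int, int]  # 0-based half-open, plus strand
    orientation: str  # 'forward' | 'reverse' in transcript orientation
    tm: float
    mutated_positions: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PrimerSet:
    gene_id: str
    terminus: str
    guide: GuideCandidate | None
    mutation_plan: SilentMutationPlan | None
    left_primers: list[Primer] = field(default_factory=list)  # P1 + P2 (or P2A/P2B)
    right_primers: list[Primer] = field(default_factory=list)  # P3 (or P3A/P3B) + P4
    genotyping: list[Primer] = field(default_factory=list)
    arm_lengths: tuple[int | None, int | None] = (None, None)
    needs_split: tuple[bool, bool] = (False, False)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Silent mutations

_STANDARD_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_CODON_AA = {c: str(Seq(c).translate()) for c in _STANDARD_CODONS}
_SYNONYMS: dict[str, list[str]] = {}
for _c, _aa in _CODON_AA.items():
    _SYNONYMS[_c] = sorted(c for c, aa in _CODON_AA.items() if aa == _aa and c != _c)

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _genomic_to_cds_offset(transcript: TranscriptModel, pos: int) -> int | None:
    running = 0
    segs = transcript.cds_segments
    if transcript.strand == "+":
        for s, e in segs:
            if s <= pos < e:
                return running + (pos - s)
            running += e - s
    else:
        for s, e in reversed(segs):
            if s <= pos < e:
                return running + (e - 1 - pos)
            running += e - s
    return None


def _cds_offset_to_genomic_base(transcript: TranscriptModel, off: int) -> int:
    """Plus-strand position of CDS base ``off`` (0-based, transcript order)."""
    remaining = off
    if transcript.strand == "+":
        for s, e in transcript.cds_segments:
            if remaining < e - s:
                return s + remaining
            remaining -= e - s
    else:
        for s, e in reversed(transcript.cds_segments):
            if remaining < e - s:
                return e - 1 - remaining
            remaining -= e - s
    raise ValueError(f"CDS base offset {off} out of range")


def _splice_guard_ok(
    transcript: TranscriptModel, pos: int, params: PrimerParameters
) -> bool:
    """False when a change at plus-strand ``pos`` sits too close to an
    exon-intron junction (exonic side: < exon_junction_guard nt; intronic
    side: < intron_junction_guard nt). Junctions are internal CDS-segment
    boundaries only."""
    segs = transcript.cds_segments
    exonic = any(s <= pos < e for s, e in segs)
    for i, (s, e) in enumerate(segs):
        has_upstream_intron = i > 0
        has_downstream_intron = i < len(segs) - 1
        if exonic and s <= pos < e:
            if has_upstream_intron and pos - s < params.exon_junction_guard:
                return False
            if has_downstream_intron and (e - 1 - pos) < params.exon_junction_guard:
                return False
            return True
    if not exonic:
        lo, hi = segs[0][0], segs[-1][1]
        if lo <= pos < hi:  # intronic: guard near both flanking exon edges
            for i in range(len(segs) - 1):
                gap_lo, gap_hi = segs[i][1], segs[i + 1][0]
                if gap_lo <= pos < gap_hi:
                    if pos - gap_lo < params.intron_junction_guard:
                        return False
                    if gap_hi - 1 - pos < params.intron_junction_guard:
                        return False
                    return True
    return True  # UTR/flank: freely changeable


def guide_footprint(guide: GuideCandidate, seed_length: int = 8):
    """(pam_gg_positions, seed_positions) on the plus strand, PAM-proximal
    seed bases first."""
    p = guide.protospacer_genomic_start
    k = len(guide.protospacer)
    if guide.strand == "+":
        pam_gg = [p + k + 1, p + k + 2]
        seed = [p + k - 1 - j for j in range(seed_length)]
    else:
        pam_gg = [p - 2, p - 3]
        seed = [p + j for j in range(seed_length)]
    return pam_gg, seed


def plan_silent_mutations(
    guide: GuideCandidate,
    transcript: TranscriptModel,
    genome: GenomeAssembly,
    params: PrimerParameters | None = None,
) -> SilentMutationPlan:
    """Choose 4-5 synonymous nucleotide changes under the guide seed and PAM.

    Codons overlapping the footprint are swapped for the synonymous codon
    changing the most footprint bases; intron/UTR footprint bases are changed
    freely (transversion) outside the splice-junction guard. If fewer than
    four changes are achievable the plan carries INSUFFICIENT_SILENT_MUTATIONS.
    """
    params = params or PrimerParameters()
    chrom_seq = genome.chromosomes[transcript.chromosome]
    pam_gg, seed = guide_footprint(guide, params.seed_length)
    footprint = set(pam_gg) | set(seed)
    priority = pam_gg + seed

    plan = SilentMutationPlan()
    mutated: dict[int, str] = {}
    handled_codons: set[int] = set()

    def minus(base: str) -> str:
        return revcomp(base)

    for pos in priority:
        if plan.count >= params.silent_mutation_min:
            break
        if pos in mutated or pos < 0 or pos >= len(chrom_seq):
            continue
        cds_off = _genomic_to_cds_offset(transcript, pos)
        if cds_off is None:
            # intron or UTR: free change, guarded near splice junctions
            if not _splice_guard_ok(transcript, pos, params):
                continue
            ref = chrom_seq[pos]
            if ref == "N":
                continue
            alt = _TRANSVERSION[ref]
            mutated[pos] = alt
            plan.mutations.append(
                SilentMutation(pos, ref, alt, None, None, None)
            )
            continue
        codon_idx = cds_off // 3
        if codon_idx in handled_codons:
            continue
        handled_codons.add(codon_idx)
        codon_positions = [
            _cds_offset_to_genomic_base(transcript, 3 * codon_idx + j)
            for j in range(3)
        ]
        if transcript.strand == "+":
            codon = "".join(chrom_seq[g] for g in codon_positions)
        else:
            codon = "".join(minus(chrom_seq[g]) for g in codon_positions)
        if "N" in codon or codon not in _SYNONYMS:
            continue
        allowed = [
            _splice_guard_ok(transcript, g, params) for g in codon_positions
        ]
        best = None
        for alt_codon in _SYNONYMS[codon]:
            changes = [j for j in range(3) if alt_codon[j] != codon[j]]
            if any(not allowed[j] for j in changes):
                continue
            fp = sum(1 for j in changes if codon_positions[j] in footprint)
            if fp == 0:
                continue
            if plan.count + len(changes) > params.silent_mutation_max:
                continue  # hard cap: never exceed the 4-5 change budget
            key = (-fp, len(changes), alt_codon)
            if best is None or key < best[0]:
                best = (key, alt_codon, changes)
        if best is None:
            continue
        _, alt_codon, changes = best
        assert _CODON_AA[alt_codon] == _CODON_AA[codon]  # synonymy re-check
        for j in changes:
            g = codon_positions[j]
            ref = chrom_seq[g]
            alt = alt_codon[j] if transcript.strand == "+" else minus(alt_codon[j])
            mutated[g] = alt
            plan.mutations.append(
                SilentMutation(g, ref, alt, codon_idx + 1, codon, alt_codon)
            )

    plan.pam_disrupted = any(m.genomic_pos in set(pam_gg) for m in plan.mutations)
    if plan.count < params.silent_mutation_min:
        plan.warnings.append("INSUFFICIENT_SILENT_MUTATIONS")
    return plan


# ---------------------------------------------------------------------------
# Anchored (junction) primers


def needs_split(
    mutation_distances_from_junction,
    max_len: int = 35,
    min_unmodified_3prime: int = 15,
) -> bool:
    """True when a single anchored primer cannot hold every mutation while
    keeping ``min_unmodified_3prime`` clean 3'-terminal bases (d=1 is the base
    adjacent to the junction; the anchored primer's 3' end is junction-distal)."""
    d = list(mutation_distances_from_junction)
    if not d:
        return False
    if min(d) < 1:
        raise ValueError("distances are 1-based from the junction")
    return max(d) > max_len - min_unmodified_3prime


def _mutation_distance(
    pos: int, junction: int, transcript_strand: str, side: str
) -> int | None:
    """Distance (>=1) of a plus-strand position from the junction on the given
    arm side, measured in transcript orientation; None if on the other side."""
    upstream = side == "left"
    if (transcript_strand == "+") == upstream:
        d = junction - pos  # positions below the junction
        return d if d >= 1 else None
    d = pos - junction + 1  # positions at/above the junction
    return d if d >= 1 else None


def _sense_slice(
    genome: GenomeAssembly,
    chrom: str,
    junction: int,
    length: int,
    transcript_strand: str,
    side: str,
    position_map: dict[int, str],
) -> tuple[str, tuple[int, int]]:
    """Transcript-sense sequence of the ``length`` bases adjacent to the
    junction on one side, mutations applied. For the upstream (left) side the
    string ends at the junction; for the downstream (right) side it starts
    there. Returns (sequence, plus-strand span)."""
    upstream = side == "left"
    low_side = (transcript_strand == "+") == upstream
    if low_side:
        a, b = junction - length, junction
    else:
        a, b = junction, junction + length
    n = genome.length(chrom)
    if a < 0 or b > n:
        raise ValueError("anchored-primer region off contig")
    bases = list(genome.sequence(chrom, a, b))
    for pos, alt in position_map.items():
        if a <= pos < b:
            bases[pos - a] = alt
    plus = "".join(bases)
    sense = plus if transcript_strand == "+" else revcomp(plus)
    return sense, (a, b)


def anchored_primers(
    side: str,
    insertion_point: InterbaseCoord,
    mutation_plan: SilentMutationPlan,
    genome: GenomeAssembly,
    transcript_strand: str,
    params: PrimerParameters | None = None,
) -> list[Primer]:
    """P2/P3 (single design) or P2A+P2B / P3A+P3B (split design).

    Both anchored primers point away from the junction, so the 15-clean-base
    3' rule binds exactly when mutations sit far from the junction.
    """
    params = params or PrimerParameters()
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    J = insertion_point.offset
    chrom = insertion_point.chromosome
    upstream = side == "left"
    pos_map = mutation_plan.as_position_map()
    side_muts = {
        pos: alt
        for pos, alt in pos_map.items()
        if _mutation_distance(pos, J, transcript_strand, side) is not None
    }
    distances = {
        pos: _mutation_distance(pos, J, transcript_strand, side)
        for pos in side_muts
    }
    max_d = max(distances.values(), default=0)

    def build(name: str, d_lo: int, d_hi: int, muts: dict[int, str]) -> Primer:
        """Primer covering junction distances [d_lo, d_hi] with ``muts``."""
        length = d_hi
        sense, span = _sense_slice(
            genome, chrom, J, length, transcript_strand, side, muts
        )
        if upstream:
            # sense string ends at the junction: index for distance d is length-d
            sub = sense[: d_hi - d_lo + 1] if d_lo > 1 else sense
            seq = revcomp(sub)
            orientation = "reverse"
        else:
            sub = sense[d_lo - 1 : d_hi]
            seq = sub
            orientation = "forward"
        # narrow the genomic span to the sub-slice actually used
        a, b = span
        if d_lo > 1:
            trim = d_lo - 1
            low_side = (transcript_strand == "+") == upstream
            a, b = (a, b - trim) if low_side else (a + trim, b)
        prim = Primer(
            name=name,
            sequence=seq,
            chromosome=chrom,
            span=(a, b),
            orientation=orientation,
            tm=melting_temperature(seq),
            mutated_positions=sorted(p for p in muts if a <= p < b),
        )
        if len(seq) > params.anchored_len_max:
            prim.warnings.append("AUX_PRIMER_LONG")
        return prim

    single_name = "P2" if upstream else "P3"
    if not needs_split(
        distances.values(), params.anchored_len_max, params.min_unmodified_3prime
    ):
        length = min(
            params.anchored_len_max,
            max(params.anchored_len_min, max_d + params.min_unmodified_3prime),
        )
        return [build(single_name, 1, length, side_muts)]

    # split design: inner primer anchored at the junction carries only
    # mutations within its allowance; the auxiliary primer carries them all,
    # overlapping the inner primer by `overlap` nt
    inner_len = params.anchored_len_max
    allowance = inner_len - params.min_unmodified_3prime
    inner_muts = {p: a for p, a in side_muts.items() if distances[p] <= allowance}
    a1 = inner_len - params.overlap + 1
    a2 = max(max_d + params.min_unmodified_3prime, a1 + params.anchored_len_min - 1)
    aux_muts = {p: a for p, a in side_muts.items() if a1 <= distances[p] <= a2}
    inner_name, aux_name = ("P2B", "P2A") if upstream else ("P3B", "P3A")
    inner = build(inner_name, 1, inner_len, inner_muts)
    aux = build(aux_name, a1, a2, aux_muts)
    return [aux, inner] if upstream else [inner, aux]


# ---------------------------------------------------------------------------
# Outer, specificity and genotyping primers


@dataclass
class SearchRegion:
    """Outer-primer search geometry: the arm anchors at ``anchor`` and extends
    in plus-strand ``direction`` (-1: lower coordinates, +1: higher)."""

    chromosome: str
    anchor: int
    direction: int  # -1 or +1


def check_primer_specificity(primer: Primer, genome: GenomeAssembly) -> bool:
    """Accept a primer iff its sequence occurs exactly once genome-wide."""
    ok = exact_occurrences(primer.sequence, genome) == 1
    if not ok and "NONSPECIFIC_PRIMER" not in primer.warnings:
        primer.warnings.append("NONSPECIFIC_PRIMER")
    return ok


def pick_outer_primer(
    partner_primer: Primer,
    search_region: SearchRegion,
    genome: GenomeAssembly,
    params: PrimerParameters | None = None,
    name: str = "P1",
    orientation: str = "forward",
) -> Primer | None:
    """Outer primer (P1/P4) Tm-matched to its anchored partner, amplicon in
    [arm_min, arm_max], expanded in ``expand_step`` increments to
    ``arm_hard_max`` when no specific Tm-matched candidate exists."""
    params = params or PrimerParameters()
    chrom = search_region.chromosome
    anchor = search_region.anchor
    n = genome.length(chrom)
    # region slice covering the deepest possible search, oriented so that
    # index 0 is the arm-distal end
    # NN Tm and GC are reverse-complement invariant, so the plus-strand region
    # is scored directly for either primer orientation
    if search_region.direction < 0:
        region_lo = max(0, anchor - params.arm_hard_max)
        region = genome.sequence(chrom, region_lo, anchor)
        truncated = region_lo > anchor - params.arm_hard_max

        def locate(D: int, length: int) -> tuple[int, int]:
            return anchor - D, anchor - D + length

        def region_start(span: tuple[int, int]) -> int:
            return span[0] - region_lo
    else:
        region_hi = min(n, anchor + params.arm_hard_max)
        region = genome.sequence(chrom, anchor, region_hi)
        truncated = region_hi < anchor + params.arm_hard_max

        def locate(D: int, length: int) -> tuple[int, int]:
            return anchor + D - length, anchor + D

        def region_start(span: tuple[int, int]) -> int:
            return span[0] - anchor
    thermo = _RegionThermo(region)
    avail = len(region)
    fallback: tuple[tuple, Primer] | None = None
    checks = 0
    searched_to = params.arm_min - 1
    arm_cap = params.arm_max
    while arm_cap <= params.arm_hard_max:
        cands = []
        for D in range(max(params.arm_min, searched_to + 1), min(arm_cap, avail) + 1):
            for length in range(params.outer_len_min, params.outer_len_max + 1):
                if length > D:
                    continue
                start = region_start(locate(D, length))
                tm = thermo.tm(start, length)
                if math.isnan(tm):
                    continue
                gc = thermo.gc_percent(start, length)
                if not (params.outer_gc_min <= gc <= params.outer_gc_max):
                    continue
                dtm = abs(tm - partner_primer.tm)
                if dtm > params.tm_tolerance:
                    continue
                cands.append((dtm, abs(D - params.arm_min), D, length, tm))
        cands.sort(key=lambda t: (t[0], t[1], locate(t[2], t[3])[0]))
        for dtm, _, D, length, tm in cands:
            span = locate(D, length)
            plus_slice = genome.sequence(chrom, *span)
            seq = plus_slice if search_region.direction < 0 else revcomp(plus_slice)
            prim = Primer(
                name=name,
                sequence=seq,
                chromosome=chrom,
                span=span,
                orientation=orientation,
                tm=tm,
            )
            if fallback is None or (dtm,) < fallback[0]:
                fallback = ((dtm,), prim)
            if checks < params.max_specificity_checks:
                checks += 1
                if check_primer_specificity(prim, genome):
                    return prim
        searched_to = min(arm_cap, avail)
        if searched_to >= min(params.arm_hard_max, avail):
            break
        arm_cap += params.expand_step
    if fallback is not None:
        prim = fallback[1]
        if "NONSPECIFIC_PRIMER" not in prim.warnings:
            prim.warnings.append("NONSPECIFIC_PRIMER")
        return prim
    none_marker = Primer(
        name=name,
        sequence="",
        chromosome=chrom,
        span=(anchor, anchor),
        orientation=orientation,
        tm=float("nan"),
        warnings=["NO_VALID_OUTER_PRIMER"] + (["SEARCH_REGION_TRUNCATED"] if truncated else []),
    )
    return none_marker


def design_genotyping_primers(
    edited_region_span: tuple[str, int, int],
    genome: GenomeAssembly,
    params: PrimerParameters | None = None,
) -> tuple[Primer | None, Primer | None, list[str]]:
    """Forward/reverse genotyping pair flanking the whole edited region, each
    searched within a fixed outside margin (never expanded inward)."""
    params = params or PrimerParameters()
    chrom, lo, hi = edited_region_span
    n = genome.length(chrom)
    warnings: list[str] = []

    def best_in_margin(margin_lo, margin_hi, is_forward, tm_ref, name):
        cands = []
        region = genome.sequence(chrom, margin_lo, margin_hi)
        thermo = _RegionThermo(region)
        for start in range(0, len(region)):
            for length in range(params.outer_len_min, params.outer_len_max + 1):
                if start + length > len(region):
                    continue
                tm = thermo.tm(start, length)
                if math.isnan(tm):
                    continue
                gc = thermo.gc_percent(start, length)
                if not (params.outer_gc_min <= gc <= params.outer_gc_max):
                    continue
                cands.append((abs(tm - tm_ref), start, length, tm))
        cands.sort(key=lambda t: (t[0], t[1]))
        checks = 0
        fallback = None
        for dtm, start, length, tm in cands:
            span = (margin_lo + start, margin_lo + start + length)
            plus_slice = genome.sequence(chrom, *span)
            seq = plus_slice if is_forward else revcomp(plus_slice)
            prim = Primer(
                name=name,
                sequence=seq,
                chromosome=chrom,
                span=span,
                orientation="forward" if is_forward else "reverse",
                tm=tm,
            )
            if fallback is None:
                fallback = prim
            if checks < params.max_specificity_checks:
                checks += 1
                if check_primer_specificity(prim, genome):
                    return prim
        return fallback

    f_lo = max(0, lo - params.geno_margin)
    if f_lo == 0 and lo - params.geno_margin < 0:
        warnings.append("GENO_LEFT_MARGIN_TRUNCATED")
    geno_f = (
        best_in_margin(f_lo, lo, True, params.tm_target, "GENO_F") if lo - f_lo >= params.outer_len_min else None
    )
    r_hi = min(n, hi + params.geno_margin)
    if r_hi == n and hi + params.geno_margin > n:
        warnings.append("GENO_RIGHT_MARGIN_TRUNCATED")
    tm_ref = geno_f.tm if geno_f is not None else params.tm_target
    geno_r = (
        best_in_margin(hi, r_hi, False, tm_ref, "GENO_R") if r_hi - hi >= params.outer_len_min else None
    )
    if geno_f is None:
        warnings.append("NO_GENOTYPING_FORWARD")
    if geno_r is None:
        warnings.append("NO_GENOTYPING_REVERSE")
    elif geno_f is not None and abs(geno_f.tm - geno_r.tm) > params.tm_tolerance:
        warnings.append("GENOTYPING_TM_MISMATCH")
    return geno_f, geno_r, warnings


def design_primer_set(
    gene_id: str,
    terminus: str,
    guide: GuideCandidate | None,
    transcript: TranscriptModel,
    insertion_point: InterbaseCoord,
    genome: GenomeAssembly,
    params: PrimerParameters | None = None,
) -> PrimerSet:
    """Full primer set for one insertion site: silent-mutation plan, anchored
    P2/P3 (split when needed), outer P1/P4 and the genotyping pair."""
    params = params or PrimerParameters()
    plan = (
        plan_silent_mutations(guide, transcript, genome, params)
        if guide is not None
        else SilentMutationPlan()
    )
    strand = transcript.strand
    left = anchored_primers("left", insertion_point, plan, genome, strand, params)
    right = anchored_primers("right", insertion_point, plan, genome, strand, params)
    J = insertion_point.offset
    chrom = insertion_point.chromosome
    # transcript-upstream arm sits at lower plus coords iff strand is '+'
    left_dir = -1 if strand == "+" else +1
    p1 = pick_outer_primer(
        left[0],  # distal-most left primer (P2 or P2A)
        SearchRegion(chrom, J, left_dir),
        genome,
        params,
        name="P1",
        orientation="forward",
    )
    p4 = pick_outer_primer(
        right[-1],
        SearchRegion(chrom, J, -left_dir),
        genome,
        params,
        name="P4",
        orientation="reverse",
    )
    warnings: list[str] = list(plan.warnings)
    spans = [p.span for p in left + right]
    arm_left = arm_right = None
    if p1 is not None and p1.sequence:
        spans.append(p1.span)
        arm_left = abs(J - (p1.span[0] if left_dir < 0 else p1.span[1]))
    if p4 is not None and p4.sequence:
        spans.append(p4.span)
        arm_right = abs((p4.span[1] if left_dir < 0 else p4.span[0]) - J)
    for p in [p1, p4] + left + right:
        if p is not None:
            warnings.extend(w for w in p.warnings if w not in warnings)
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    geno_f, geno_r, geno_warn = design_genotyping_primers((chrom, lo, hi), genome, params)
    warnings.extend(w for w in geno_warn if w not in warnings)
    left_all = ([p1] if p1 is not None and p1.sequence else []) + left
    right_all = right + ([p4] if p4 is not None and p4.sequence else [])
    return PrimerSet(
        gene_id=gene_id,
        terminus=terminus,
        guide=guide,
        mutation_plan=plan,
        left_primers=left_all,
        right_primers=right_all,
        genotyping=[p for p in (geno_f, geno_r) if p is not None],
        arm_lengths=(arm_left, arm_right),
        needs_split=(len(left) == 2, len(right) == 2),
        warnings=warnings,
    )
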