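"""SpCas9 guide enumeration, filtering, classification and selection.

Candidates are 20-nt protospacers adjacent to an NGG PAM, scanned on both
strands of a +/-50 bp window around each insertion point. The blunt cut sits
3 bp 5' of the PAM, between protospacer positions 17 and 18. Composition
filters: GC within [25, 80]% inclusive (protospacer only), no homopolymer of
7+ bases, PAM != GGG and the base 3' of the PAM != G. A TTTT run does not
reject a guide but restricts it to in-vitro transcription (a T4 tract
terminates Pol III in vivo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeAssembly, InterbaseCoord, revcomp


@dataclass
class DesignParameters:
    window_halfwidth: int = 50
    protospacer_length: int = 20
    pam: str = "NGG"
    cut_offset: int = 3  # nt 5' of the PAM
    gc_min: float = 25.0
    gc_max: float = 80.0
    homopolymer_reject_length: int = 7
    polyt_run: int = 4
    offtarget_max_mismatches: int = 3

    def __post_init__(self):
        if self.gc_min >= self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        for name in (
            "window_halfwidth",
            "protospacer_length",
            "cut_offset",
            "homopolymer_reject_length",
            "polyt_run",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.offtarget_max_mismatches < 0:
            raise ValueError("offtarget_max_mismatches must be >= 0")


@dataclass
class Window:
    """A plus-strand genomic window with 1-nt PAM-context padding."""

    chromosome: str
    seq: str
    start: int  # genomic offset of seq[0]
    truncated: bool = False
    left_pad: str | None = None  # base immediately 5' of the window, or None
    right_pad: str | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class GuideCandidate:
    protospacer: str  # protospacer-strand sense
    pam: str
    pam_next_base: str | None
    strand: str  # '+' or '-'
    protospacer_genomic_start: int  # 0-based plus-strand leftmost base
    cut_point: InterbaseCoord
    gc_percent: float
    transcription_class: str | None = None  # 'in_vivo' | 'in_vitro_only'
    reject_reasons: set[str] = field(default_factory=set)
    offtarget_count: int | None = None
    distance_to_insertion: int | None = None

    @property
    def passed(self) -> bool:
        return not self.reject_reasons


@dataclass
class GuideSelection:
    in_vivo_best: GuideCandidate | None = None
    in_vitro_extra: GuideCandidate | None = None
    no_guide_flag: bool = False


def extract_window(
    genome: GenomeAssembly, insertion_point: InterbaseCoord, halfwidth: int = 50
) -> Window:
    """Plus-strand slice [ins - halfwidth, ins + halfwidth), truncated at
    contig ends (flagged), with one base of padding each side for PAM-context
    checks."""
    chrom = insertion_point.chromosome
    n = genome.length(chrom)
    lo = max(0, insertion_point.offset - halfwidth)
    hi = min(n, insertion_point.offset + halfwidth)
    truncated = (lo != insertion_point.offset - halfwidth) or (
        hi != insertion_point.offset + halfwidth
    )
    return Window(
        chromosome=chrom,
        seq=genome.sequence(chrom, lo, hi),
        start=lo,
        truncated=truncated,
        left_pad=genome.sequence(chrom, lo - 1, lo) if lo > 0 else None,
        right_pad=genome.sequence(chrom, hi, hi + 1) if hi < n else None,
    )


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def enumerate_candidates(
    window: Window, params: DesignParameters | None = None
) -> list[GuideCandidate]:
    """Every protospacer+NGG placement fitting fully inside the window, both
    strands, unfiltered. Placements containing N are disqualified."""
    params = params or DesignParameters()
    k = params.protospacer_length
    w = window.seq
    out: list[GuideCandidate] = []
    for i in range(len(w) - (k + 3) + 1):
        # plus strand: 20-mer at i, PAM at [i+k, i+k+3)
        proto, pam = w[i : i + k], w[i + k : i + k + 3]
        if pam[1:] == "GG" and "N" not in proto and "N" not in pam:
            nxt = w[i + k + 3] if i + k + 3 < len(w) else window.right_pad
            start = window.start + i
            out.append(
                GuideCandidate(
                    protospacer=proto,
                    pam=pam,
                    pam_next_base=nxt,
                    strand="+",
                    protospacer_genomic_start=start,
                    cut_point=InterbaseCoord(window.chromosome, start + k - params.cut_offset),
                    gc_percent=gc_percent(proto),
                )
            )
        # minus strand: plus-strand CCN at [i, i+3), 20-mer at [i+3, i+3+k)
        pam_rc, proto_rc = w[i : i + 3], w[i + 3 : i + 3 + k]
        if pam_rc[:2] == "CC" and "N" not in proto_rc and "N" not in pam_rc:
            nxt_plus = w[i - 1] if i > 0 else window.left_pad
            nxt = revcomp(nxt_plus) if nxt_plus is not None else None
            start = window.start + i + 3
            out.append(
                GuideCandidate(
                    protospacer=revcomp(proto_rc),
                    pam=revcomp(pam_rc),
                    pam_next_base=nxt,
                    strand="-",
                    protospacer_genomic_start=start,
                    cut_point=InterbaseCoord(window.chromosome, start + params.cut_offset),
                    gc_percent=gc_percent(proto_rc),
                )
            )
    return out


def _has_homopolymer(seq: str, min_len: int) -> bool:
    run, prev = 0, ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        if run >= min_len:
            return True
    return False


def apply_filters(
    candidate: GuideCandidate, params: DesignParameters | None = None
) -> GuideCandidate:
    """Attach reject reasons and the transcription class in place."""
    params = params or DesignParameters()
    p = candidate.protospacer
    if not (params.gc_min <= candidate.gc_percent <= params.gc_max):
        candidate.reject_reasons.add("gc_out_of_range")
    if _has_homopolymer(p, params.homopolymer_reject_length):
        candidate.reject_reasons.add("homopolymer")
    if candidate.pam == "GGG":
        candidate.reject_reasons.add("pam_ggg")
    if candidate.pam_next_base == "G":
        candidate.reject_reasons.add("pam_context_g")
    elif candidate.pam_next_base is None:
        # off-contig context cannot be verified: fail conservatively
        candidate.reject_reasons.add("pam_context_unknown")
    candidate.transcription_class = (
        "in_vitro_only" if "T" * params.polyt_run in p else "in_vivo"
    )
    return candidate


def cut_coordinate(candidate: GuideCandidate) -> InterbaseCoord:
    """Blunt-cut boundary between protospacer positions 17|18 (own sense)."""
    return candidate.cut_point


def rank_and_select(
    candidates: list[GuideCandidate], insertion_point: InterbaseCoord
) -> GuideSelection:
    """Rank passing candidates by (off-target count, cut-to-insertion distance,
    plus strand first, genomic start) and pick the best in-vivo guide, plus an
    in-vitro-only extra when its cut is strictly closer."""
    passing = [c for c in candidates if c.passed]
    for c in passing:
        c.distance_to_insertion = abs(c.cut_point.offset - insertion_point.offset)
    if not passing:
        return GuideSelection(no_guide_flag=True)
    ranked = sorted(
        passing,
        key=lambda c: (
            c.offtarget_count if c.offtarget_count is not None else float("inf"),
            c.distance_to_insertion,
            0 if c.strand == "+" else 1,
            c.protospacer_genomic_start,
        ),
    )
    in_vivo = next((c for c in ranked if c.transcription_class == "in_vivo"), None)
    in_vitro = next(
        (c for c in ranked if c.transcription_class == "in_vitro_only"), None
    )
    extra = None
    if in_vitro is not None and (
        in_vivo is None or in_vitro.distance_to_insertion < in_vivo.distance_to_insertion
    ):
        extra = in_vitro
    return GuideSelection(in_vivo_best=in_vivo, in_vitro_extra=extra)


def design_guides_for_site(
    genome: GenomeAssembly,
    insertion_point: InterbaseCoord,
    offtarget_index=None,
    params: DesignParameters | None = None,
) -> GuideSelection:
    """extract -> enumerate -> filter -> count off-targets -> rank/select."""
    from .offtargets import count_offtargets

    params = params or DesignParameters()
    window = extract_window(genome, insertion_point, params.window_halfwidth)
    if len(window.seq) < params.protospacer_length + 3:
        return GuideSelection(no_guide_flag=True)
    candidates = [
        apply_filters(c, params) for c in enumerate_candidates(window, params)
    ]
    if offtarget_index is not None:
        for c in candidates:
            if c.passed:
                c.offtarget_count = count_offtargets(
                    c.protospacer,
                    offtarget_index,
                    params.offtarget_max_mismatches,
                    on_target_location=(
                        window.chromosome,
                        c.strand,
                        c.protospacer_genomic_start,
                    ),
                )
    else:
        for c in candidates:
            c.offtarget_count = 0
    return rank_and_select(candidates, insertion_point)
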