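"""End-to-end knock-in design: insertion sites -> guides -> primers.

One row is emitted per gene per terminus; genes with no usable guide are
reported with ``no_guide`` set rather than dropped, and per-gene failures are
collected as log entries so a batch run always completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import ProteinFeatureSet, make_insertion_specs
from .genome import GenomeAssembly, TranscriptModel
from .guides import DesignParameters, GuideSelection, design_guides_for_site
from .offtargets import PamSiteIndex, build_index
from .primers import PrimerParameters, PrimerSet, design_primer_set


@dataclass
class GeneDesign:
    gene_id: str
    terminus: str
    boundary_residue: int
    insertion_interbase: int
    insertion_coord_1based: int
    warning_flags: list[str]
    notes: list[str]
    selection: GuideSelection
    primer_set: PrimerSet | None = None


@dataclass
class DesignRun:
    designs: list[GeneDesign] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)  # per-gene log lines


def design_gene(
    genome: GenomeAssembly,
    transcript: TranscriptModel,
    features: ProteinFeatureSet,
    index: PamSiteIndex | None,
    guide_params: DesignParameters | None = None,
    primer_params: PrimerParameters | None = None,
    with_primers: bool = True,
) -> list[GeneDesign]:
    guide_params = guide_params or DesignParameters()
    n_spec, c_spec = make_insertion_specs(transcript, features, genome)
    out = []
    for spec in (n_spec, c_spec):
        selection = design_guides_for_site(
            genome, spec.genomic_point, index, guide_params
        )
        primer_set = None
        guide = selection.in_vivo_best or selection.in_vitro_extra
        if with_primers and guide is not None:
            primer_set = design_primer_set(
                transcript.gene_id,
                spec.terminus,
                guide,
                transcript,
                spec.genomic_point,
                genome,
                primer_params,
            )
        out.append(
            GeneDesign(
                gene_id=transcript.gene_id,
                terminus=spec.terminus,
                boundary_residue=spec.boundary_residue,
                insertion_interbase=spec.genomic_point.offset,
                insertion_coord_1based=spec.five_prime_coord,
                warning_flags=sorted(spec.warning_flags),
                notes=list(spec.notes),
                selection=selection,
                primer_set=primer_set,
            )
        )
    return out


def design_batch(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    features: dict[str, ProteinFeatureSet],
    guide_params: DesignParameters | None = None,
    primer_params: PrimerParameters | None = None,
    with_primers: bool = True,
    with_offtargets: bool = True,
) -> DesignRun:
    index = build_index(genome) if with_offtargets else None
    run = DesignRun()
    for t in transcripts:
        fs = features.get(t.gene_id)
        if fs is None:
            run.errors.append(f"{t.gene_id}: no protein feature record; skipped")
            continue
        try:
            run.designs.extend(
                design_gene(
                    genome, t, fs, index, guide_params, primer_params, with_primers
                )
            )
        except Exception as exc:  # per-gene failures never abort the batch
            run.errors.append(f"{t.gene_id}: {exc}")
    return run


def _guide_columns(prefix: str, g) -> dict:
    if g is None:
        return {}
    return {
        f"{prefix}_sequence": g.protospacer,
        f"{prefix}_pam": g.pam,
        f"{prefix}_strand": g.strand,
        f"{prefix}_start_1based": g.protospacer_genomic_start + 1,
        f"{prefix}_cut_interbase": g.cut_point.offset,
        f"{prefix}_gc_percent": round(g.gc_percent, 1),
        f"{prefix}_class": g.transcription_class,
        f"{prefix}_offtargets": g.offtarget_count,
        f"{prefix}_distance": g.distance_to_insertion,
    }


def design_table(run: DesignRun) -> pd.DataFrame:
    rows = []
    for d in run.designs:
        row = {
            "gene_id": d.gene_id,
            "terminus": d.terminus,
            "boundary_residue": d.boundary_residue,
            "insertion_interbase": d.insertion_interbase,
            "insertion_coord_1based": d.insertion_coord_1based,
            "no_guide": d.selection.no_guide_flag,
            "warnings": ";".join(d.warning_flags + d.notes),
        }
        row.update(_guide_columns("guide", d.selection.in_vivo_best))
        row.update(_guide_columns("ivt_guide", d.selection.in_vitro_extra))
        if d.primer_set is not None:
            row["arm_left"] = d.primer_set.arm_lengths[0]
            row["arm_right"] = d.primer_set.arm_lengths[1]
            row["split_design"] = (
                "left" * d.primer_set.needs_split[0]
                + ("," if all(d.primer_set.needs_split) else "")
                + "right" * d.primer_set.needs_split[1]
            )
            row["silent_mutations"] = (
                d.primer_set.mutation_plan.count if d.primer_set.mutation_plan else 0
            )
            row["primer_warnings"] = ";".join(d.primer_set.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


def primer_table(run: DesignRun) -> pd.DataFrame:
    rows = []
    for d in run.designs:
        ps = d.primer_set
        if ps is None:
            continue
        for p in ps.left_primers + ps.right_primers + ps.genotyping:
            rows.append(
                {
                    "gene_id": d.gene_id,
                    "terminus": d.terminus,
                    "primer": p.name,
                    "sequence": p.sequence,
                    "tm": round(p.tm, 2),
                    "chromosome": p.chromosome,
                    "start_1based": p.span[0] + 1,
                    "end_1based": p.span[1],
                    "orientation": p.orientation,
                    "mutated_positions": ";".join(
                        str(x + 1) for x in p.mutated_positions
                    ),
                    "warnings": ";".join(p.warnings),
                }
            )
    return pd.DataFrame(rows)


def design_bed(run: DesignRun) -> list[tuple]:
    """BED6 records of insertion points and selected guide spans."""
    rows = []
    for d in run.designs:
        chrom = None
        g = d.selection.in_vivo_best or d.selection.in_vitro_extra
        if g is not None:
            chrom = g.cut_point.chromosome
            rows.append(
                (
                    chrom,
                    g.protospacer_genomic_start,
                    g.protospacer_genomic_start + len(g.protospacer),
                    f"{d.gene_id}|{d.terminus}|guide",
                    g.offtarget_count or 0,
                    g.strand,
                )
            )
    return rows
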