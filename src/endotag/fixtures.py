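"""Deterministic synthetic genomes, gene models, feature tables and allele
inventories with generator-side ground truth.

Everything downstream (coordinate mapping, guide and primer design, survey
statistics) is exercised against these fixtures, so each generator records
the analytically expected answers *while constructing* the data — truth
coordinates come from the generator's own base-by-base bookkeeping, not from
the coordinate-walking code under test. Identical seed and spec give
byte-identical outputs.

The inventory generator's default mixture (alleles per gene 63.1/19.7/8.3/8.9%,
tag positions C 62.9 / N 33.7 / internal 2.9 / multiple 0.5%, tags GFP 44.0 /
mNeonGreen 17.0 / FLAG 30.1% with the remainder split across other tags, a
linear accrual of ~203 newly tagged genes per year from 2020, and an
exponential-saturation discovery curve) emulates the published C. elegans
tagged-allele landscape; it is a synthetic stand-in with known truth, not the
real supplementary inventory.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ProteinFeatureSet
from .genome import GenomeAssembly, TranscriptModel, revcomp
from .survey import AlleleRecord

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class FixtureManifest:
    """Specification of a synthetic genome + gene-model fixture."""

    seed: int = 0
    n_genes: int = 20
    n_chromosomes: int = 1
    gc: float = 0.36  # roughly nematode-like base composition
    codons_min: int = 80
    codons_max: int = 250
    exons_min: int = 1
    exons_max: int = 5
    intron_min: int = 48
    intron_max: int = 200
    minus_strand_prob: float = 0.5
    intergenic: int = 2400
    chrom_pad: int = 1600
    p_init_met: float = 0.25
    p_signal: float = 0.2
    p_signal_propeptide: float = 0.3  # propeptide after signal, conditional
    p_transit: float = 0.05
    p_c_propeptide: float = 0.12
    p_lipidation_n: float = 0.05
    p_lipidation_c: float = 0.05
    p_chain: float = 0.3


@dataclass
class GeneTruth:
    """Generator-side expected values for one synthetic gene."""

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    protein_length: int
    protein: str
    n_boundary_residue: int
    c_boundary_residue: int
    n_interbase: int
    c_interbase: int
    n_five_prime_coord: int
    c_five_prime_coord: int
    n_lipidation_adjusted: bool = False
    c_lipidation_adjusted: bool = False
    no_processing: bool = False


@dataclass
class GenomeFixture:
    manifest: FixtureManifest
    genome: GenomeAssembly
    transcripts: list[TranscriptModel]
    features: dict[str, ProteinFeatureSet]
    truth: list[GeneTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_cds(rng: np.random.Generator, n_residues: int) -> str:
    """ATG + random sense codons + a stop; translates cleanly."""
    body = rng.choice(_SENSE_CODONS, size=n_residues - 1)
    stop = rng.choice(_STOPS)
    return "ATG" + "".join(body) + stop


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds[: len(cds) - 3]).translate())


def _gene_features(
    rng: np.random.Generator, m: FixtureManifest, length: int
) -> tuple[ProteinFeatureSet, dict]:
    """Draw a maturation scenario and record the expected boundaries the
    scenario implies (computed here by construction, before the pipeline)."""
    init_met = bool(rng.random() < m.p_init_met)
    signal = transit = None
    propeptides: list[tuple[int, int]] = []
    n_expect = 2 if init_met else 1
    draw = rng.random()
    if draw < m.p_signal:
        s = int(rng.integers(16, 31))
        signal = (1, s)
        n_expect = s + 1
        if rng.random() < m.p_signal_propeptide:
            pro_len = int(rng.integers(5, 16))
            propeptides.append((s + 1, s + pro_len))
            n_expect = s + pro_len + 1
    elif draw < m.p_signal + m.p_transit:
        t = int(rng.integers(10, 41))
        transit = (1, t)
        n_expect = t + 1
    c_expect = length
    if rng.random() < m.p_c_propeptide:
        a = int(rng.integers(length - 20, length - 5))
        propeptides.append((a, length))
        c_expect = a - 1
    # chain is drawn against the pre-lipidation boundaries, matching how the
    # pipeline orders processing inference before the lipidation offset
    chain = None
    if rng.random() < m.p_chain:
        chain = (n_expect, c_expect)
    lipidation: list[tuple[int, str]] = []
    n_adj = c_adj = False
    if rng.random() < m.p_lipidation_n and n_expect + 12 < c_expect:
        site = n_expect  # |site - boundary| = 0 -> rule fires
        lipidation.append((site, "N"))
        n_expect = site + 6
        n_adj = True
    if rng.random() < m.p_lipidation_c and n_expect + 12 < c_expect:
        site = c_expect
        lipidation.append((site, "C"))
        c_expect = site - 6
        c_adj = True
    fs = ProteinFeatureSet(
        uniprot_id="SYN" + format(rng.integers(0, 10**6), "06d"),
        protein_length=length,
        init_met_removed=init_met,
        signal_peptide=signal,
        transit_peptide=transit,
        propeptides=propeptides,
        chain=chain,
        lipidation_sites=lipidation,
    )
    no_processing = not fs.has_n_processing
    expect = {
        "n": n_expect,
        "c": c_expect,
        "n_adj": n_adj,
        "c_adj": c_adj,
        "no_processing": no_processing,
    }
    return fs, expect


def make_genome_fixture(manifest: FixtureManifest) -> GenomeFixture:
    """Generate a synthetic genome with clean ORFs, gene models, maturation
    features and a truth table of expected insertion coordinates."""
    m = manifest
    rng = np.random.default_rng(m.seed)
    chrom_parts: dict[str, list[str]] = {
        f"chrS{i + 1}": [] for i in range(m.n_chromosomes)
    }
    chrom_len: dict[str, int] = {name: 0 for name in chrom_parts}
    for name in chrom_parts:
        pad = _random_dna(rng, m.chrom_pad, m.gc)
        chrom_parts[name].append(pad)
        chrom_len[name] += len(pad)

    transcripts: list[TranscriptModel] = []
    features: dict[str, ProteinFeatureSet] = {}
    truths: list[GeneTruth] = []
    chrom_names = list(chrom_parts)
    for gi in range(m.n_genes):
        gene_id = f"sg-{gi + 1}"
        chrom = chrom_names[gi % len(chrom_names)]
        n_res = int(rng.integers(m.codons_min, m.codons_max + 1))
        cds = _random_cds(rng, n_res)
        protein = _translate(cds)
        assert "*" not in protein and protein.startswith("M")

        n_ex = int(rng.integers(m.exons_min, m.exons_max + 1))
        if n_ex > 1:
            cuts = sorted(
                rng.choice(np.arange(1, len(cds)), size=n_ex - 1, replace=False)
            )
        else:
            cuts = []
        bounds = [0] + [int(c) for c in cuts] + [len(cds)]
        exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            "GT"
            + _random_dna(rng, int(rng.integers(m.intron_min, m.intron_max + 1)) - 4, m.gc)
            + "AG"
            for _ in range(n_ex - 1)
        ]
        # assemble the gene block in transcript orientation, tracking the
        # block offset of every CDS base (generator-side truth bookkeeping)
        block: list[str] = []
        cds_block_offsets: list[int] = []
        off = 0
        for i, ex in enumerate(exons):
            block.append(ex)
            cds_block_offsets.extend(range(off, off + len(ex)))
            off += len(ex)
            if i < len(introns):
                block.append(introns[i])
                off += len(introns[i])
        block_seq = "".join(block)
        block_len = len(block_seq)
        strand = "-" if rng.random() < m.minus_strand_prob else "+"

        gene_start = chrom_len[chrom]
        if strand == "+":
            plus_block = block_seq
            cds2genomic = [gene_start + o for o in cds_block_offsets]
        else:
            plus_block = revcomp(block_seq)
            cds2genomic = [gene_start + block_len - 1 - o for o in cds_block_offsets]
        chrom_parts[chrom].append(plus_block)
        chrom_len[chrom] += block_len
        spacer = _random_dna(rng, m.intergenic, m.gc)
        chrom_parts[chrom].append(spacer)
        chrom_len[chrom] += len(spacer)

        # CDS segments in ascending plus-strand coordinates
        seg_bounds = list(zip(bounds, bounds[1:]))
        segs = []
        for a, b in seg_bounds:
            block_a = cds_block_offsets[a]
            block_b = cds_block_offsets[b - 1] + 1
            if strand == "+":
                segs.append((gene_start + block_a, gene_start + block_b))
            else:
                segs.append(
                    (gene_start + block_len - block_b, gene_start + block_len - block_a)
                )
        segs.sort()
        transcripts.append(
            TranscriptModel(
                transcript_id=f"t.{gene_id}",
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                cds_segments=segs,
            )
        )

        fs, expect = _gene_features(rng, m, n_res)
        features[gene_id] = fs

        def boundary_truth(cds_offset: int) -> tuple[int, int]:
            """(interbase, 1-based 5'-adjacent base) by direct lookup."""
            if cds_offset == 0:
                ib = cds2genomic[0] if strand == "+" else cds2genomic[0] + 1
            else:
                ib = (
                    cds2genomic[cds_offset - 1] + 1
                    if strand == "+"
                    else cds2genomic[cds_offset - 1]
                )
            return ib, (ib if strand == "+" else ib + 1)

        n_ib, n_fp = boundary_truth(3 * (expect["n"] - 1))
        c_ib, c_fp = boundary_truth(3 * expect["c"])
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                transcript_id=f"t.{gene_id}",
                chromosome=chrom,
                strand=strand,
                protein_length=n_res,
                protein=protein,
                n_boundary_residue=expect["n"],
                c_boundary_residue=expect["c"],
                n_interbase=n_ib,
                c_interbase=c_ib,
                n_five_prime_coord=n_fp,
                c_five_prime_coord=c_fp,
                n_lipidation_adjusted=expect["n_adj"],
                c_lipidation_adjusted=expect["c_adj"],
                no_processing=expect["no_processing"],
            )
        )

    for name in chrom_parts:
        tail = _random_dna(rng, m.chrom_pad, m.gc)
        chrom_parts[name].append(tail)
    genome = GenomeAssembly(
        {name: "".join(parts) for name, parts in chrom_parts.items()},
        assembly_name=f"synthetic-seed{m.seed}",
    )
    return GenomeFixture(m, genome, transcripts, features, truths)


def write_genome_fixture(fix: GenomeFixture, out_dir) -> dict[str, Path]:
    """Serialize a fixture as FASTA + GFF3 + feature TSV + truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "features": out / "protein_features.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.txt",
    }
    with open(paths["fasta"], "w") as fh:
        for name, seq in fix.genome.chromosomes.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for t in fix.transcripts:
            lo = t.cds_segments[0][0] + 1
            hi = t.cds_segments[-1][1]
            fh.write(
                f"{t.chromosome}\tendotag\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                f"ID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chromosome}\tendotag\tmRNA\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id};canonical=1\n"
            )
            ordered = (
                t.cds_segments if t.strand == "+" else list(reversed(t.cds_segments))
            )
            running = 0
            for s, e in ordered:
                phase = (3 - running % 3) % 3
                fh.write(
                    f"{t.chromosome}\tendotag\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                    f"{phase}\tID=cds.{t.transcript_id};Parent={t.transcript_id}\n"
                )
                running += e - s
    rows = []
    for gid, fs in fix.features.items():
        rows.append(
            {
                "uniprot_id": fs.uniprot_id,
                "gene_id": gid,
                "length": fs.protein_length,
                "init_met_removed": int(fs.init_met_removed),
                "signal_end": fs.signal_peptide[1] if fs.signal_peptide else "",
                "transit_end": fs.transit_peptide[1] if fs.transit_peptide else "",
                "propeptides": ";".join(f"{a}-{b}" for a, b in fs.propeptides),
                "chain": f"{fs.chain[0]}-{fs.chain[1]}" if fs.chain else "",
                "lipidation": ";".join(f"{p}:{c}" for p, c in fs.lipidation_sites),
            }
        )
    pd.DataFrame(rows).to_csv(paths["features"], sep="\t", index=False)
    fix.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        for k, v in vars(fix.manifest).items():
            fh.write(f"{k}={v}\n")
    return paths


def plant_offtarget(
    genome: GenomeAssembly,
    protospacer: str,
    mismatches: int,
    location: tuple[str, str, int],
    occupied: list[tuple[str, int, int]] | None = None,
) -> GenomeAssembly:
    """Overwrite the genome so that exactly one protospacer+NGG site with the
    requested Hamming distance sits at ``location`` (chromosome, strand,
    plus-strand protospacer start)."""
    chrom, strand, start = location
    site = list(protospacer)
    for j in range(mismatches):  # deterministic, spread across the protospacer
        pos = (3 * j + 1) % len(site)
        site[pos] = _TRANSVERSION[site[pos]]
    site_seq = "".join(site)
    assert sum(a != b for a, b in zip(site_seq, protospacer)) == mismatches
    if strand == "+":
        lo, hi = start, start + len(site_seq) + 3
        payload = site_seq + "TGG"
    else:
        lo, hi = start - 3, start + len(site_seq)
        payload = revcomp(site_seq + "TGG")
    for oc, olo, ohi in occupied or []:
        if oc == chrom and lo < ohi and olo < hi:
            raise ValueError(f"planted site [{lo},{hi}) collides with [{olo},{ohi})")
    seq = genome.chromosomes[chrom]
    if lo < 0 or hi > len(seq):
        raise ValueError("planted site out of bounds")
    chroms = dict(genome.chromosomes)
    chroms[chrom] = seq[:lo] + payload + seq[hi:]
    return GenomeAssembly(chroms, assembly_name=genome.assembly_name)


# ---------------------------------------------------------------------------
# Inventory fixture


@dataclass
class InventorySpec:
    seed: int = 0
    n_genes: int = 1000
    alleles_per_gene_pct: tuple = (63.1, 19.7, 8.3, 8.9)  # 1 / 2 / 3 / 4+
    position_pct: dict = field(
        default_factory=lambda: {"C": 62.9, "N": 33.7, "internal": 2.9, "multiple": 0.5}
    )
    tag_pct: dict = field(
        default_factory=lambda: {
            "GFP": 44.0,
            "mNeonGreen": 17.0,
            "FLAG": 30.1,
            "mScarlet": 5.0,
            "AID": 3.9,
        }
    )
    year_start: int = 2013
    year_linear_from: int = 2020
    year_end: int = 2025
    genes_per_year: float = 203.0  # linear accrual after year_linear_from
    cgc_fraction: float = 0.3  # alleles also present in the stock-center list
    n_duplicates: int = 0  # injected redundant records (dedup must remove)


def largest_remainder(total: int, percentages) -> list[int]:
    """Integer allocation of ``total`` matching ``percentages`` as closely as
    integer counts allow (Hamilton apportionment)."""
    pcts = np.asarray(list(percentages), dtype=float)
    raw = total * pcts / pcts.sum()
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


@dataclass
class InventoryFixture:
    spec: InventorySpec
    records: list[AlleleRecord]
    truth: dict


def make_inventory_fixture(spec: InventorySpec | None = None) -> InventoryFixture:
    """Synthetic tagged-allele inventory with exactly allocated distributions.

    Counts are assigned by largest-remainder apportionment, so the realized
    alleles-per-gene and tag-position distributions are the spec percentages
    up to integer resolution; the generator records the realized values as
    truth.
    """
    spec = spec or InventorySpec()
    rng = np.random.default_rng(spec.seed)
    bucket_counts = largest_remainder(spec.n_genes, spec.alleles_per_gene_pct)
    alleles_per_gene = [1] * bucket_counts[0] + [2] * bucket_counts[1] + [
        3
    ] * bucket_counts[2] + [4] * bucket_counts[3]
    n_alleles = sum(alleles_per_gene)
    pos_names = list(spec.position_pct)
    pos_counts = largest_remainder(n_alleles, spec.position_pct.values())
    tag_names = list(spec.tag_pct)
    tag_counts = largest_remainder(n_alleles, spec.tag_pct.values())
    remaining_pos = dict(zip(pos_names, pos_counts))
    remaining_tag = dict(zip(tag_names, tag_counts))

    # first-tagging years: linear accrual after year_linear_from, a ramp before
    years = list(range(spec.year_start, spec.year_end + 1))
    n_linear_years = spec.year_end - spec.year_linear_from + 1
    linear_total = int(round(spec.genes_per_year * n_linear_years))
    linear_total = min(linear_total, spec.n_genes)
    ramp_total = spec.n_genes - linear_total
    ramp_years = [y for y in years if y < spec.year_linear_from]
    ramp_weights = np.arange(1, len(ramp_years) + 1, dtype=float)
    ramp_counts = (
        largest_remainder(ramp_total, 100 * ramp_weights / ramp_weights.sum())
        if ramp_years
        else []
    )
    year_pool: list[int] = []
    for y, c in zip(ramp_years, ramp_counts):
        year_pool.extend([y] * c)
    per_linear = largest_remainder(
        linear_total, [1.0] * n_linear_years
    )
    for y, c in zip(range(spec.year_linear_from, spec.year_end + 1), per_linear):
        year_pool.extend([y] * c)
    assert len(year_pool) == spec.n_genes

    records: list[AlleleRecord] = []
    serial = 0
    # multi-allele genes are assigned first, while tag/position diversity is
    # still available, so (tag, position) combos stay unique within a gene and
    # dedup only ever removes deliberately injected duplicates; drawing the
    # most abundant remaining categories first preserves the exact global
    # counts without end-game starvation
    gene_order = sorted(range(spec.n_genes), key=lambda i: -alleles_per_gene[i])
    for gi in gene_order:
        n_all = alleles_per_gene[gi]
        gene = f"sgene-{gi + 1}"
        first_year = year_pool[gi]
        used: set[tuple[str, str]] = set()
        for k in range(n_all):
            choice = None
            for pos in sorted(remaining_pos, key=lambda p: (-remaining_pos[p], p)):
                if remaining_pos[pos] <= 0:
                    continue
                for tag in sorted(remaining_tag, key=lambda t: (-remaining_tag[t], t)):
                    if remaining_tag[tag] > 0 and (tag, pos) not in used:
                        choice = (tag, pos)
                        break
                if choice:
                    break
            tag, pos = choice
            remaining_pos[pos] -= 1
            remaining_tag[tag] -= 1
            used.add((tag, pos))
            serial += 1
            positions = (
                frozenset({"N", "C"}) if pos == "multiple" else frozenset({pos})
            )
            tags = frozenset({tag, "HA"}) if pos == "multiple" else frozenset({tag})
            year = min(first_year + k, spec.year_end)
            records.append(
                AlleleRecord(
                    gene_id=gene,
                    gene_name=gene,
                    allele_designation=f"syn{serial}",
                    tags=tags,
                    tag_positions=positions,
                    source="CGC" if rng.random() < spec.cgc_fraction else "literature",
                    year=int(year),
                )
            )
    base_len = len(records)
    for j in range(spec.n_duplicates):  # redundant re-publications
        src = records[j % base_len]
        serial += 1
        records.append(
            AlleleRecord(
                gene_id=src.gene_id,
                gene_name=src.gene_name,
                allele_designation=f"syn{serial}",
                tags=src.tags,
                tag_positions=src.tag_positions,
                source=src.source,
                year=min((src.year or spec.year_end) + 2, 2100),
            )
        )

    pos_real = {
        name: 100.0 * cnt / n_alleles for name, cnt in zip(pos_names, pos_counts)
    }
    apg_real = {
        k: 100.0 * c / spec.n_genes
        for k, c in zip(("1", "2", "3", "4+"), bucket_counts)
    }
    truth = {
        "n_genes": spec.n_genes,
        "n_alleles": n_alleles,
        "alleles_per_gene_pct": apg_real,
        "position_pct": pos_real,
        "n_duplicates": spec.n_duplicates,
    }
    return InventoryFixture(spec, records, truth)


def write_inventory(records: list[AlleleRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "gene_name": r.gene_name,
            "allele": r.allele_designation or "",
            "tags": ";".join(sorted(r.tags)),
            "positions": ";".join(sorted(r.tag_positions)),
            "source": r.source,
            "year": r.year if r.year is not None else "",
            "reference": r.reference_id or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def discovery_series(
    n_papers: int,
    g_max: float = 1700.0,
    tau: float = 1052.7,
    noise_sd: float = 0.0,
    seed: int = 0,
    step: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative newly discovered genes vs papers screened, following an
    exponential-saturation curve with optional Gaussian noise (forced
    monotone)."""
    rng = np.random.default_rng(seed)
    x = np.arange(step, n_papers + 1, step, dtype=float)
    y = g_max * (1.0 - np.exp(-x / tau))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
        y = np.maximum.accumulate(np.maximum(y, 0.0))
    return x, y
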