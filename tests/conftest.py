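import numpy as np
import pytest

from endotag.fixtures import FixtureManifest, make_genome_fixture
from endotag.genome import GenomeAssembly, TranscriptModel


@pytest.fixture(scope="session")
def small_fixture():
    """30 synthetic genes, mixed strands/exon counts/features."""
    return make_genome_fixture(FixtureManifest(seed=11, n_genes=30))


@pytest.fixture(scope="session")
def sweep_fixture():
    """1,000 synthetic genes spanning both strands, 1-5 exons and every
    maturation-feature combination; shared by the acceptance sweeps."""
    return make_genome_fixture(FixtureManifest(seed=101, n_genes=1000))


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return GenomeAssembly({"chrT": seq})


def make_single_exon_gene(genome, start_1based=101, n_codons=8, chrom="chrT"):
    """Plant a clean single-exon ORF on the plus strand at a 1-based position
    and return the matching TranscriptModel. Mutates the assembly in place."""
    rng = np.random.default_rng(7)
    sense = [c for c in
             [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
             if c not in ("TAA", "TAG", "TGA")]
    cds = "ATG" + "".join(rng.choice(sense, size=n_codons - 2)) + "TAA"
    s = start_1based - 1
    seq = genome.chromosomes[chrom]
    genome.chromosomes[chrom] = seq[:s] + cds + seq[s + len(cds):]
    return TranscriptModel(
        transcript_id="t.toy",
        gene_id="toy",
        chromosome=chrom,
        strand="+",
        cds_segments=[(s, s + len(cds))],
    )
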