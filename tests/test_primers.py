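"""Silent mutations, anchored/split primers, Tm, outer and genotyping primers."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from endotag.genome import GenomeAssembly, InterbaseCoord, protein_sequence, revcomp
from endotag.guides import GuideCandidate
from endotag.pipeline import design_gene
from endotag.primers import (
    Primer,
    PrimerParameters,
    SearchRegion,
    SilentMutation,
    SilentMutationPlan,
    _RegionThermo,
    anchored_primers,
    design_genotyping_primers,
    guide_footprint,
    melting_temperature,
    needs_split,
    pick_outer_primer,
    plan_silent_mutations,
)
from tests.conftest import make_single_exon_gene


class TestMeltingTemperature:
    def test_matches_biopython_nearest_neighbor(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(18, 36)))
            assert melting_temperature(s) == pytest.approx(
                mt.Tm_NN(s, nn_table=mt.DNA_NN3), abs=1e-9
            )

    def test_region_prefix_sums_agree_with_direct_formula(self):
        rng = np.random.default_rng(4)
        region = "".join(rng.choice(list("ACGT"), size=400))
        thermo = _RegionThermo(region)
        for start, length in [(0, 20), (100, 18), (250, 27), (373, 27)]:
            assert thermo.tm(start, length) == pytest.approx(
                melting_temperature(region[start : start + length]), abs=1e-9
            )

    def test_n_containing_window_is_nan(self):
        thermo = _RegionThermo("ACGTN" + "ACGT" * 10)
        assert np.isnan(thermo.tm(0, 20))


def plus_guide(start, strand="+"):
    return GuideCandidate(
        protospacer="N/A-not-used-in-plan"[:20].replace("/", "A"),
        pam="TGG",
        pam_next_base="A",
        strand=strand,
        protospacer_genomic_start=start,
        cut_point=InterbaseCoord("chrT", start + 17 if strand == "+" else start + 3),
        gc_percent=50.0,
    )


class TestPlanSilentMutations:
    def test_mixed_codons_reach_target_and_lys_uses_its_only_synonym(self, toy_genome):
        # CDS 100.. : ATG then alternating Lys/Leu codons under the guide seed
        t = make_single_exon_gene(toy_genome, start_1based=101, n_codons=40)
        seq = toy_genome.chromosomes["chrT"]
        toy_genome.chromosomes["chrT"] = seq[:103] + "AAGCTT" * 6 + seq[103 + 36:]
        plan = plan_silent_mutations(plus_guide(103), t, toy_genome)
        assert 4 <= plan.count <= 5
        for m in plan.mutations:
            if m.codon_before == "AAG":
                assert m.codon_after == "AAA"  # the only Lys synonym
            assert str(Seq(m.codon_before).translate()) == str(
                Seq(m.codon_after).translate()
            )

    def test_met_trp_only_footprint_yields_insufficient_warning(self, toy_genome):
        t = make_single_exon_gene(toy_genome, start_1based=101, n_codons=40)
        seq = toy_genome.chromosomes["chrT"]
        toy_genome.chromosomes["chrT"] = seq[:103] + "TGG" * 12 + seq[103 + 36:]
        plan = plan_silent_mutations(plus_guide(103), t, toy_genome)
        assert plan.count < 4
        assert "INSUFFICIENT_SILENT_MUTATIONS" in plan.warnings

    def test_mutations_are_synonymous_by_retranslation(self, small_fixture):
        """Applying every emitted plan to the genome leaves the protein
        byte-identical (silent by construction)."""
        fix = small_fixture
        checked = 0
        for t in fix.transcripts:
            designs = design_gene(
                fix.genome, t, fix.features[t.gene_id], None, with_primers=False
            )
            for d in designs:
                g = d.selection.in_vivo_best or d.selection.in_vitro_extra
                if g is None:
                    continue
                plan = plan_silent_mutations(g, t, fix.genome)
                if not plan.mutations:
                    continue
                chrom = t.chromosome
                seq = list(fix.genome.chromosomes[chrom])
                for m in plan.mutations:
                    assert seq[m.genomic_pos] == m.ref
                    seq[m.genomic_pos] = m.alt
                edited = GenomeAssembly({chrom: "".join(seq)})
                assert protein_sequence(t, edited) == protein_sequence(t, fix.genome)
                assert plan.count <= 5
                checked += 1
        assert checked > 20

    def test_minus_strand_guides_get_plans_too(self, small_fixture):
        fix = small_fixture
        seen_minus = 0
        for t in fix.transcripts:
            designs = design_gene(
                fix.genome, t, fix.features[t.gene_id], None, with_primers=False
            )
            for d in designs:
                g = d.selection.in_vivo_best
                if g is None or g.strand != "-":
                    continue
                plan = plan_silent_mutations(g, t, fix.genome)
                footprint = set().union(*guide_footprint(g))
                codon_positions = {m.genomic_pos for m in plan.mutations}
                assert plan.count >= 1
                seen_minus += 1
        assert seen_minus > 5


class TestNeedsSplit:
    @pytest.mark.parametrize(
        "distances,expected",
        [({4, 7, 9, 11}, False), ({22, 26}, True), ({20}, False), (set(), False)],
    )
    def test_trigger_threshold(self, distances, expected):
        assert needs_split(distances) is expected

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            needs_split({0, 5})


def mutation_plan_at(genome, junction, distances, side="left", strand="+"):
    """Plan with mutations at the given junction distances (left/upstream)."""
    seq = genome.chromosomes["chrT"]
    muts = []
    for d in distances:
        if (strand == "+") == (side == "left"):
            g = junction - d
        else:
            g = junction + d - 1
        ref = seq[g]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        muts.append(SilentMutation(g, ref, alt, None, None, None))
    return SilentMutationPlan(mutations=muts)


class TestAnchoredPrimers:
    def test_single_design_p2_is_revcomp_of_mutated_upstream_slice(self, toy_genome):
        J = 1000
        plan = mutation_plan_at(toy_genome, J, [5, 8])
        (p2,) = anchored_primers(
            "left", InterbaseCoord("chrT", J), plan, toy_genome, "+"
        )
        assert p2.name == "P2" and len(p2.sequence) == 30
        mutated = list(toy_genome.sequence("chrT", J - 30, J))
        for m in plan.mutations:
            mutated[m.genomic_pos - (J - 30)] = m.alt
        assert p2.sequence == revcomp("".join(mutated))
        # 15-base rule: mutations at d=5,8 stay clear of the 3' end (d 16..30)
        assert all(J - p <= 15 for p in p2.mutated_positions)

    def test_split_design_geometry_and_mutation_placement(self, toy_genome):
        J = 1000
        plan = mutation_plan_at(toy_genome, J, [22, 24])
        p2a, p2b = anchored_primers(
            "left", InterbaseCoord("chrT", J), plan, toy_genome, "+"
        )
        assert (p2a.name, p2b.name) == ("P2A", "P2B")
        overlap = min(p2a.span[1], p2b.span[1]) - max(p2a.span[0], p2b.span[0])
        assert 18 <= overlap <= 22
        assert sorted(p2a.mutated_positions) == [J - 24, J - 22]
        assert p2b.mutated_positions == []
        assert p2b.sequence == revcomp(toy_genome.sequence("chrT", J - 35, J))

    def test_unmutated_right_side_gives_plain_p3(self, toy_genome):
        J = 1000
        (p3,) = anchored_primers(
            "right", InterbaseCoord("chrT", J), SilentMutationPlan(), toy_genome, "+"
        )
        assert p3.name == "P3" and p3.mutated_positions == []
        assert p3.sequence == toy_genome.sequence("chrT", J, J + 30)

    def test_minus_strand_orientation(self, toy_genome):
        J = 1000
        (p2,) = anchored_primers(
            "left", InterbaseCoord("chrT", J), SilentMutationPlan(), toy_genome, "-"
        )
        # minus-strand transcript: upstream arm sits at higher plus coords and
        # the reverse primer reads the plus strand directly
        assert p2.span == (J, J + 30)
        assert p2.sequence == toy_genome.sequence("chrT", J, J + 30)


def _rand_genome(seed, n):
    rng = np.random.default_rng(seed)
    return GenomeAssembly({"chrT": "".join(rng.choice(list("ACGT"), size=n))})


class TestOuterPrimers:
    def test_amplicon_lands_in_default_window(self):
        g = _rand_genome(9, 24_000)
        partner = Primer("P2", "X" * 30, "chrT", (11_970, 12_000), "reverse", 60.0)
        p1 = pick_outer_primer(partner, SearchRegion("chrT", 12_000, -1), g)
        assert p1 is not None and p1.sequence
        arm = 12_000 - p1.span[0]
        assert 500 <= arm <= 1000
        assert abs(p1.tm - 60.0) <= 3.0
        assert p1.sequence == g.sequence("chrT", *p1.span)  # forward on plus

    def test_repeat_region_triggers_expansion(self):
        g = _rand_genome(10, 24_000)
        seq = g.chromosomes["chrT"]
        g.chromosomes["chrT"] = seq[:11_000] + "AT" * 500 + seq[12_000:]
        partner = Primer("P2", "X" * 30, "chrT", (11_970, 12_000), "reverse", 60.0)
        p1 = pick_outer_primer(partner, SearchRegion("chrT", 12_000, -1), g)
        arm = 12_000 - p1.span[0]
        assert arm > 1000 and arm <= 10_000

    def test_reverse_direction_returns_minus_strand_primer(self):
        g = _rand_genome(11, 24_000)
        partner = Primer("P3", "X" * 30, "chrT", (12_000, 12_030), "forward", 60.0)
        p4 = pick_outer_primer(
            partner, SearchRegion("chrT", 12_000, +1), g, name="P4",
            orientation="reverse",
        )
        arm = p4.span[1] - 12_000
        assert 500 <= arm <= 1000
        assert p4.sequence == revcomp(g.sequence("chrT", *p4.span))


class TestGenotypingPrimers:
    def test_amplicon_strictly_contains_edited_region(self):
        g = _rand_genome(12, 24_000)
        lo, hi = 10_000, 11_500
        f, r, warn = design_genotyping_primers(("chrT", lo, hi), g)
        assert f is not None and r is not None and not warn
        assert f.span[1] <= lo and r.span[0] >= hi
        assert abs(f.tm - r.tm) <= 3.0

    def test_margin_off_contig_warns(self):
        g = _rand_genome(13, 3_000)
        f, r, warn = design_genotyping_primers(("chrT", 200, 2_800), g)
        assert "GENO_LEFT_MARGIN_TRUNCATED" in warn
        assert "GENO_RIGHT_MARGIN_TRUNCATED" in warn


class TestGuideImmunity:
    def test_repaired_allele_not_recut_after_mutation_plan(self, small_fixture):
        """With a disrupted PAM or >=3 seed changes, the selected guide has no
        exact protospacer+NGG match left at the edited locus."""
        fix = small_fixture
        checked = 0
        for t in fix.transcripts:
            designs = design_gene(
                fix.genome, t, fix.features[t.gene_id], None, with_primers=False
            )
            for d in designs:
                g = d.selection.in_vivo_best or d.selection.in_vitro_extra
                if g is None:
                    continue
                plan = plan_silent_mutations(g, t, fix.genome)
                pam_gg, seed = guide_footprint(g)
                seed_changes = sum(m.genomic_pos in set(seed) for m in plan.mutations)
                if not (plan.pam_disrupted or seed_changes >= 3):
                    continue
                chrom = t.chromosome
                seq = list(fix.genome.chromosomes[chrom])
                for m in plan.mutations:
                    seq[m.genomic_pos] = m.alt
                lo = max(0, g.protospacer_genomic_start - 30)
                hi = min(len(seq), g.protospacer_genomic_start + 60)
                window = "".join(seq[lo:hi])
                target = g.protospacer
                for hay in (window, revcomp(window)):
                    for hit in re.finditer(re.escape(target), hay):
                        pam = hay[hit.end() : hit.end() + 3]
                        assert not (len(pam) == 3 and pam[1:] == "GG"), (
                            t.gene_id,
                            d.terminus,
                        )
                checked += 1
        assert checked > 10
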