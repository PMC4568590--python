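"""Stitched alignments, the four classifier features, and ancestral
conservation inference."""

import math
from io import StringIO

import numpy as np
import pytest
from Bio import Phylo
from Bio.Seq import Seq

from smorf import conservation_features as cf
from smorf.io_formats import AlignmentBlock, ConservationTrack, \
    GenomeInterval, TranscriptModel
from smorf.orf_catalog import ORFRecord


def make_orf(seq="ATG" + "GCA" * 8 + "TAA", start=100, strand="+"):
    return ORFRecord(id="orf1", transcript_ids=["t1"],
                     genomic_intervals=[GenomeInterval("chr1", start,
                                                       start + len(seq),
                                                       strand)],
                     transcript_start=0, transcript_end=len(seq),
                     nt_seq=seq, aa_seq=str(Seq(seq[:-3]).translate()))


def block_for(orf, species_rows, ref_row=None, start=None):
    rows = {"ref": ref_row or orf.nt_seq}
    rows.update(species_rows)
    return AlignmentBlock("chr1", start if start is not None
                          else orf.genomic_intervals[0].start, "ref", rows)


class TestStitchAndFlag:
    def test_identical_species_clean_flags(self):
        orf = make_orf()
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": orf.nt_seq})])
        fl = st.flags["spA"]
        assert fl.coverage_fraction == 1.0
        assert not fl.has_frameshift_indel
        assert not fl.has_premature_stop
        assert fl.start_conserved and fl.stop_conserved

    def test_one_nt_insertion_is_frameshifting(self):
        orf = make_orf()
        ref = orf.nt_seq[:9] + "-" + orf.nt_seq[9:]
        sp = orf.nt_seq[:9] + "T" + orf.nt_seq[9:]
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": sp}, ref_row=ref)])
        assert st.flags["spA"].has_frameshift_indel

    def test_three_nt_deletion_is_not_frameshifting(self):
        orf = make_orf()
        sp = orf.nt_seq[:9] + "---" + orf.nt_seq[12:]
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": sp})])
        assert not st.flags["spA"].has_frameshift_indel

    def test_no_blocks_means_zero_coverage(self):
        orf = make_orf()
        st = cf.stitch_and_flag(orf, [])
        assert st.species == []

    def test_premature_stop_detected(self):
        orf = make_orf()
        sp = orf.nt_seq[:12] + "TAA" + orf.nt_seq[15:]
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": sp})])
        assert st.flags["spA"].has_premature_stop

    def test_minus_strand_rows_in_transcript_orientation(self):
        seq = "ATG" + "GGG" * 8 + "TGA"
        g = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        orf = make_orf(seq=seq, strand="-")
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": g},
                                                ref_row=g)])
        assert st.rows["spA"] == seq


class TestFrameConservationCount:
    def test_mixed_species_counted_by_hand(self):
        """4 species: one frameshifted, one at low coverage -> 2."""
        orf = make_orf()
        L = len(orf.nt_seq)
        ref = orf.nt_seq[:9] + "-" + orf.nt_seq[9:]
        rows = {
            "a": orf.nt_seq[:9] + "-" + orf.nt_seq[9:],       # clean
            "b": orf.nt_seq[:9] + "T" + orf.nt_seq[9:],       # frameshift
            "c": orf.nt_seq[:9] + "-" + orf.nt_seq[9:],       # clean
            "d": "." * 9 + "-" + "." * (L - 21) + orf.nt_seq[-12:],  # 0.4 cov
        }
        st = cf.stitch_and_flag(orf, [block_for(orf, rows, ref_row=ref)])
        assert cf.frame_conservation_count(st) == 2

    def test_reference_only_counts_zero(self):
        orf = make_orf()
        st = cf.stitch_and_flag(orf, [block_for(orf, {})])
        assert cf.frame_conservation_count(st) == 0

    def test_all_clean_species_counted(self):
        orf = make_orf()
        rows = {f"s{i}": orf.nt_seq for i in range(5)}
        st = cf.stitch_and_flag(orf, [block_for(orf, rows)])
        assert cf.frame_conservation_count(st) == 5

    def test_invariant_under_block_order(self):
        orf = make_orf()
        half = len(orf.nt_seq) // 2 // 3 * 3
        b1 = AlignmentBlock("chr1", 100, "ref",
                            {"ref": orf.nt_seq[:half],
                             "spA": orf.nt_seq[:half]})
        b2 = AlignmentBlock("chr1", 100 + half, "ref",
                            {"ref": orf.nt_seq[half:],
                             "spA": orf.nt_seq[half:]})
        fwd = cf.stitch_and_flag(orf, [b1, b2])
        rev = cf.stitch_and_flag(orf, [b2, b1])
        assert cf.frame_conservation_count(fwd) == \
            cf.frame_conservation_count(rev)
        assert fwd.rows == rev.rows


class TestSelectionScore:
    def test_identical_codons_closed_form(self):
        seq = "ATG" + "GCA" * 8 + "TAA"
        orf = make_orf(seq=seq)
        # score only the 10 codons of one identical species
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": seq})])
        expected = 10 * math.log2(0.55 / 0.40)
        assert cf.selection_score(st) == pytest.approx(expected)

    def test_single_nonsynonymous_event_contribution(self):
        seq = "ATG" + "GCA" * 8 + "TAA"
        sp = seq[:3] + "CCA" + seq[6:]  # Ala -> Pro at codon 2
        orf = make_orf(seq=seq)
        st = cf.stitch_and_flag(orf, [block_for(orf, {"spA": sp})])
        expected = (9 * math.log2(0.55 / 0.40)
                    + math.log2(0.14 / 0.35))
        assert cf.selection_score(st) == pytest.approx(expected)

    def test_empty_alignment_scores_zero(self):
        orf = make_orf()
        st = cf.stitch_and_flag(orf, [])
        assert cf.selection_score(st) == 0.0

    def test_table_backend_missing_id_raises(self):
        orf = make_orf()
        st = cf.stitch_and_flag(orf, [])
        with pytest.raises(KeyError, match="orf1"):
            cf.selection_score(st, backend="table", score_table={})
        assert cf.selection_score(st, backend="table",
                                  score_table={"orf1": 12.5}) == 12.5

    def test_synonymous_event_classification(self):
        assert cf.classify_codon_event("GCA", "GCG") == "synonymous"
        assert cf.classify_codon_event("GCA", "CCA") == "nonsynonymous"
        assert cf.classify_codon_event("CAA", "TAA") == "stop"
        assert cf.classify_codon_event("GCA", "GCA") == "identical"

    def test_sign_separates_simulated_evolution_classes(self, bundle):
        """Synonymous-biased fixtures score positive, frame-agnostic ones
        negative, in expectation."""
        scores = {"coding": [], "neutral": []}
        for locus, blk in zip(bundle.loci, bundle.blocks):
            if locus.cls in scores:
                st = cf.stitch_and_flag(locus.orf, [blk])
                scores[locus.cls].append(cf.selection_score(st))
        assert np.mean(scores["coding"]) > 0
        assert np.mean(scores["neutral"]) < 0


class TestStepProfiles:
    def _setup(self, inside=1.0, outside=0.0):
        seq = "ATG" + "GCA" * 30 + "TAA"
        utr = 60
        t = TranscriptModel(id="t", gene_id="g", biotype="lincRNA",
                            exons=[GenomeInterval("chr1", 0,
                                                  utr * 2 + len(seq), "+")])
        orf = ORFRecord(id="o", transcript_ids=["t"],
                        genomic_intervals=[GenomeInterval(
                            "chr1", utr, utr + len(seq), "+")],
                        transcript_start=utr, transcript_end=utr + len(seq),
                        nt_seq=seq, aa_seq=str(Seq(seq[:-3]).translate()))
        track = ConservationTrack.from_intervals(
            [("chr1", utr, utr + len(seq), inside),
             ("chr1", 0, utr, outside),
             ("chr1", utr + len(seq), 2 * utr + len(seq), outside)])
        return orf, t, track

    def test_profile_equal_to_mean_gives_zero_distance(self):
        orf, t, track = self._setup()
        start_p, stop_p = cf.orf_step_profiles(orf, t, track)
        mean = cf.build_mean_profile([start_p])
        assert cf.step_profile_distance(start_p, mean) == 0.0

    def test_flat_zero_versus_flat_one_is_sqrt_50(self):
        flat0 = np.zeros(50)
        flat1 = np.ones(50)
        assert cf.step_profile_distance(flat0, flat1) == \
            pytest.approx(math.sqrt(50))

    def test_mean_of_singleton_set_is_that_profile(self):
        orf, t, track = self._setup()
        start_p, _ = cf.orf_step_profiles(orf, t, track)
        assert np.allclose(cf.build_mean_profile([start_p]), start_p,
                           equal_nan=True)

    def test_window_sees_the_conservation_step(self):
        orf, t, track = self._setup(inside=0.9, outside=0.1)
        start_p, stop_p = cf.orf_step_profiles(orf, t, track)
        assert start_p[:25].mean() == pytest.approx(0.1)
        assert start_p[25:].mean() == pytest.approx(0.9)
        # stop window is centered on the first base of the stop codon
        assert stop_p[:25].mean() == pytest.approx(0.9)

    def test_clipped_window_distance_scaled_to_50_bases(self):
        a = np.concatenate([np.full(25, np.nan), np.zeros(25)])
        b = np.ones(50)
        assert cf.step_profile_distance(a, b) == pytest.approx(
            math.sqrt(25 * 50 / 25))


class TestAncestralConservation:
    TREE = "((ref:1,sister:1):1,outer:2);"

    def _tree(self):
        return Phylo.read(StringIO(self.TREE), "newick")

    def test_reference_only_maps_to_leaf(self):
        tree = self._tree()
        clade = cf.mrca_of_set(tree, {"ref"}, "ref")
        assert clade.name == "ref"

    def test_ref_and_sister_map_to_their_ancestor(self):
        tree = self._tree()
        clade = cf.mrca_of_set(tree, {"ref", "sister"}, "ref")
        assert {l.name for l in clade.get_terminals()} == {"ref", "sister"}

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError, match="mars"):
            cf.mrca_of_set(self._tree(), {"ref", "mars"}, "ref")

    def test_fractions_non_increasing_with_age(self):
        tree = self._tree()
        sets = [{"ref"}, {"ref"}, {"ref", "sister"},
                {"ref", "sister", "outer"}]
        fractions = cf.mrca_conservation(sets, tree, "ref")
        values = [f for _, f in fractions]
        assert values[0] == 1.0
        assert all(a >= b for a, b in zip(values, values[1:]))
        # 2 of 4 ORFs reach the ref-sister ancestor, 1 of 4 the root
        assert values[1] == pytest.approx(0.5)
        assert values[2] == pytest.approx(0.25)

    def test_conserving_species_uses_all_flags(self):
        orf = make_orf()
        clean = orf.nt_seq
        broken = orf.nt_seq[:12] + "TAA" + orf.nt_seq[15:]
        st = cf.stitch_and_flag(orf, [block_for(orf, {"sister": clean,
                                                      "outer": broken})])
        assert cf.conserving_species(st) == {"ref", "sister"}
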