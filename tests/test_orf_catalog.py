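"""ORF scanning against a brute-force oracle, grouping, classification."""

import numpy as np
import pytest

from smorf.io_formats import GenomeInterval, TranscriptModel
from smorf.orf_catalog import (AnnotationIndex, ORFRecord, STOP_CODONS,
                               classify, group_orfs, scan_orfs,
                               scan_sequence, scan_transcript)


def oracle_scan(seq, min_nt=27):
    """Independent enumeration: every AUG walked to its first in-frame
    stop; per stop keep the most upstream AUG; drop N-tainted or short
    ORFs."""
    seq = seq.upper()
    per_stop = {}
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j:j + 3]
            if codon in STOP_CODONS:
                per_stop.setdefault(j + 3, []).append(i)
                break
            j += 3
    spans = []
    for stop_end, starts in per_stop.items():
        start = min(starts)
        tainted = any("N" in seq[k:k + 3]
                      for k in range(start, stop_end, 3))
        if not tainted and stop_end - start >= min_nt:
            spans.append((start, stop_end))
    return sorted(spans)


def random_seq(rng, length, n_prob=0.0):
    bases = list("ACGT")
    seq = rng.choice(bases, size=length)
    if n_prob:
        mask = rng.random(length) < n_prob
        seq[mask] = "N"
    return "".join(seq)


class TestScanSequence:
    def test_below_minimum_length_yields_nothing(self):
        assert scan_sequence("ATGAAATAG") == []

    def test_simple_orf(self):
        seq = "ATG" + "GCA" * 8 + "TAA"
        spans = scan_sequence(seq)
        assert spans == [(0, 30)]

    def test_most_upstream_aug_wins(self):
        seq = "ATGATG" + "GCA" * 8 + "TGA"
        spans = scan_sequence(seq)
        assert spans == [(0, 33)]

    def test_orf_spanning_n_codon_is_dropped(self):
        seq = "ATG" + "GCN" + "GCA" * 8 + "TAA"
        assert scan_sequence(seq) == []

    def test_truncated_orf_without_stop_discarded(self):
        assert scan_sequence("ATG" + "GCA" * 20) == []

    @pytest.mark.parametrize("n_prob", [0.0, 0.01])
    def test_matches_bruteforce_oracle(self, rng, n_prob):
        for _ in range(200):
            seq = random_seq(rng, int(rng.integers(100, 1200)), n_prob)
            assert scan_sequence(seq) == oracle_scan(seq)


def _transcript(seq_offset, length, strand="+", biotype="lincRNA",
                tid="t1", cds=None, stranded=True):
    exon = GenomeInterval("chr1", seq_offset, seq_offset + length, strand)
    return TranscriptModel(id=tid, gene_id=f"g_{tid}", biotype=biotype,
                           exons=[exon], cds=cds, stranded=stranded)


class TestScanTranscript:
    def test_unstranded_transcript_scanned_on_both_strands(self):
        orf = "ATG" + "GCA" * 8 + "TAA"
        genome = {"chr1": "C" * 10 + orf + "C" * 10}
        t = _transcript(0, len(genome["chr1"]), stranded=False)
        records = scan_transcript(t, genome)
        strands = {r.strand for r in records}
        assert "+" in strands
        # the reverse complement of this sequence has no ORF, but both
        # orientations were scanned without error
        fwd = [r for r in records if r.strand == "+"]
        assert fwd[0].nt_seq == orf

    def test_minus_strand_orf_sequence_in_transcript_orientation(self):
        orf = "ATG" + "GGG" * 8 + "TGA"
        genome = {"chr1": "CCCCC" + _revcomp(orf) + "CCCCC"}
        t = _transcript(0, len(genome["chr1"]), strand="-")
        records = scan_transcript(t, genome)
        assert [r.nt_seq for r in records] == [orf]
        assert records[0].genomic_intervals[0].start == 5


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestGrouping:
    def _orf(self, tid, start=0, aa_shift=False):
        seq = ("ATG" + ("GTA" if aa_shift else "GCA") + "GCA" * 7 + "TAA")
        iv = GenomeInterval("chr1", 100 + start, 100 + start + 30, "+")
        from Bio.Seq import Seq
        return ORFRecord(id=f"o_{tid}", transcript_ids=[tid],
                         genomic_intervals=[iv], transcript_start=0,
                         transcript_end=30, nt_seq=seq,
                         aa_seq=str(Seq(seq[:-3]).translate()))

    def test_identical_orfs_merge_across_isoforms(self):
        groups = group_orfs([self._orf("t1"), self._orf("t2")])
        assert len(groups) == 1
        assert sorted(groups[0].transcript_ids) == ["t1", "t2"]

    def test_same_interval_different_peptide_stays_separate(self):
        groups = group_orfs([self._orf("t1"), self._orf("t2", aa_shift=True)])
        assert len(groups) == 2

    def test_disjoint_orfs_do_not_merge(self):
        groups = group_orfs([self._orf("t1"), self._orf("t2", start=60)])
        assert len(groups) == 2


class TestClassification:
    def test_bundle_categories(self, bundle):
        """Planted classes map to the expected categories end to end."""
        orfs = scan_orfs(bundle.transcripts, bundle.genome)
        index = AnnotationIndex(bundle.transcripts, bundle.genome)
        by_chain = {}
        for orf in orfs:
            orf.category = classify(orf, index)
            by_chain[orf.chain_key] = orf
        for locus in bundle.loci:
            planted = by_chain.get(locus.orf.chain_key)
            assert planted is not None, f"{locus.id} not scanned"
            expected = {
                ("coding", "protein_coding"): "annotated",
                ("coding", "lincRNA"): "lincRNA",
                ("neutral", "snoRNA"): "ncRNA",
                ("neutral", "lincRNA"): "lincRNA",
                ("pseudogene", "processed_pseudogene"): "pseudogene",
            }[(locus.cls, locus.biotype)]
            assert planted.category == expected, locus.id

    def test_every_group_gets_exactly_one_category(self, bundle):
        orfs = scan_orfs(bundle.transcripts, bundle.genome)
        index = AnnotationIndex(bundle.transcripts, bundle.genome)
        from smorf.orf_catalog import CATEGORIES
        for orf in orfs:
            assert classify(orf, index) in CATEGORIES

    def test_utr3_orf_classification(self):
        """An ORF in the 3'UTR of a canonical coding transcript with no CDS
        overlap is a dORF."""
        cds_seq = "ATG" + "CAC" * 30 + "TAA"
        dorf_seq = "ATG" + "GGG" * 8 + "TGA"
        seq = cds_seq + "CCCCC" + dorf_seq + "CCCCC"
        genome = {"chr1": seq}
        cds_iv = GenomeInterval("chr1", 0, len(cds_seq), "+")
        host = _transcript(0, len(seq), biotype="protein_coding",
                           tid="host", cds=[cds_iv])
        index = AnnotationIndex([host], genome)
        orfs = scan_orfs([host], genome)
        dorf = next(o for o in orfs
                    if o.genomic_intervals[0].start == len(cds_seq) + 5)
        assert classify(dorf, index) == "utr3"
        main = next(o for o in orfs if o.genomic_intervals[0].start == 0)
        assert classify(main, index) == "annotated"

    def test_snorna_orf_is_ncrna(self):
        orf_seq = "ATG" + "GCA" * 8 + "TAA"
        genome = {"chr1": "CC" + orf_seq + "CC"}
        t = _transcript(0, len(genome["chr1"]), biotype="snoRNA")
        index = AnnotationIndex([t], genome)
        orfs = scan_orfs([t], genome)
        assert classify(orfs[0], index) == "ncRNA"
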