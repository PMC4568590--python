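"""Scan transcripts for candidate small ORFs, group identical ORFs across
isoforms, and classify each group by its location in the transcriptome.

An ORF runs from the most upstream in-frame AUG to the first in-frame stop
codon (one candidate per stop), with a minimum genomic span of 27 nt
including the stop codon (nine codons, eight amino acids).  Non-AUG starts
are not considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import GenomeInterval, TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
NCRNA_BIOTYPES = {"miRNA", "rRNA", "tRNA", "snRNA", "snoRNA"}

CATEGORIES = ("annotated", "pseudogene", "ncRNA", "utr3", "utr5",
              "cds_overlap", "other", "lincRNA")


@dataclass
class ORFRecord:
    """A candidate ORF, possibly shared by several transcript isoforms.

    ``n_codons`` counts start through stop codon inclusive; ``aa_seq``
    carries no stop symbol.  Coordinates are spliced genomic intervals in
    ascending order; ``transcript_start``/``end`` refer to the first listed
    transcript.
    """

    id: str
    transcript_ids: list[str]
    genomic_intervals: list[GenomeInterval]
    transcript_start: int
    transcript_end: int
    nt_seq: str
    aa_seq: str
    category: str | None = None
    uses_most_upstream_aug: bool = True
    selection_score: float | None = None

    def __post_init__(self):
        if len(self.nt_seq) % 3 or len(self.nt_seq) < 27:
            raise ValueError(f"{self.id}: bad ORF length {len(self.nt_seq)}")
        if not self.nt_seq.startswith("ATG"):
            raise ValueError(f"{self.id}: does not start with ATG")
        if self.nt_seq[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: does not end with a stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.nt_seq) // 3

    @property
    def chrom(self) -> str:
        return self.genomic_intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.genomic_intervals[0].strand

    @property
    def chain_key(self) -> tuple:
        return tuple((i.chrom, i.start, i.end, i.strand)
                     for i in self.genomic_intervals)

    def genomic_positions(self) -> set[int]:
        return {p for iv in self.genomic_intervals
                for p in range(iv.start, iv.end)}

    @property
    def stop_codon_interval(self) -> GenomeInterval:
        """Genomic interval of the stop codon (may ignore splicing for the
        rare stop split across exons; the chain is spliced)."""
        positions = sorted(self.genomic_positions())
        if self.strand == "-":
            triplet = positions[:3]
        else:
            triplet = positions[-3:]
        return GenomeInterval(self.chrom, triplet[0], triplet[-1] + 1,
                              self.strand)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_sequence(seq: str, min_nt: int = 27) -> list[tuple[int, int]]:
    """Find ORF spans [start, end) on the forward frame set of ``seq``.

    For each in-frame stop codon, at most one ORF starting at the most
    upstream AUG with no intervening stop is reported.  Codons containing N
    are neither starts nor stops, and an ORF spanning one is dropped.  ORFs
    truncated by the sequence end (no stop codon) are discarded.
    """
    seq = seq.upper()
    spans = []
    for frame in range(3):
        start = None      # earliest AUG since the last stop
        ambiguous = False  # an N codon inside the open candidate
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                ambiguous = True
                continue
            if codon in STOP_CODONS:
                if start is not None and not ambiguous:
                    if i + 3 - start >= min_nt:
                        spans.append((start, i + 3))
                start, ambiguous = None, False
            elif codon == "ATG" and start is None:
                start, ambiguous = i, False
    return sorted(spans)


def scan_transcript(transcript: TranscriptModel, genome: dict[str, str],
                    min_nt: int = 27) -> list[ORFRecord]:
    """Scan one transcript (both strands if it is unstranded)."""
    records = []
    variants = [transcript]
    if not transcript.stranded:
        variants = [_oriented(transcript, "+"), _oriented(transcript, "-")]
    for t in variants:
        seq = t.spliced_sequence(genome)
        for start, end in scan_sequence(seq, min_nt=min_nt):
            nt = seq[start:end]
            aa = str(Seq(nt[:-3]).translate())
            chain = t.interval_chain(start, end)
            rid = (f"{t.chrom}:{chain[0].start}-{chain[-1].end}:{t.strand}"
                   f":{len(nt) // 3}")
            records.append(ORFRecord(
                id=rid, transcript_ids=[transcript.id],
                genomic_intervals=chain, transcript_start=start,
                transcript_end=end, nt_seq=nt, aa_seq=aa))
    return records


def _oriented(t: TranscriptModel, strand: str) -> TranscriptModel:
    exons = [GenomeInterval(e.chrom, e.start, e.end, strand) for e in t.exons]
    return TranscriptModel(id=t.id, gene_id=t.gene_id, biotype=t.biotype,
                           exons=exons, source_catalog=t.source_catalog,
                           stranded=True)


def scan_orfs(transcripts: list[TranscriptModel], genome: dict[str, str],
              min_nt: int = 27) -> list[ORFRecord]:
    """Scan all transcripts and group identical ORFs across isoforms."""
    per_transcript = []
    for t in transcripts:
        per_transcript.extend(scan_transcript(t, genome, min_nt=min_nt))
    return group_orfs(per_transcript)


def group_orfs(orfs: list[ORFRecord]) -> list[ORFRecord]:
    """One record per (genomic interval chain, amino-acid sequence) pair;
    transcript ids are concatenated."""
    groups: dict[tuple, ORFRecord] = {}
    for orf in orfs:
        key = (orf.chain_key, orf.aa_seq)
        if key in groups:
            rec = groups[key]
            for tid in orf.transcript_ids:
                if tid not in rec.transcript_ids:
                    rec.transcript_ids.append(tid)
        else:
            groups[key] = replace(orf,
                                  transcript_ids=list(orf.transcript_ids))
    return list(groups.values())


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class AnnotationIndex:
    """Precomputed lookups over the merged annotation used to classify ORFs.

    ``cds_sources`` may add CDS interval chains from further catalogs (the
    union forms the CDS reference; a 1-bp overlap counts).
    """

    def __init__(self, transcripts: list[TranscriptModel],
                 genome: dict[str, str] | None = None,
                 cds_sources: list[list[GenomeInterval]] | None = None):
        self.transcripts = {t.id: t for t in transcripts}
        self.cds_tree: dict[str, IntervalTree] = {}
        self.cds_chains: dict[tuple, str] = {}
        self.utr3: dict[str, list[GenomeInterval]] = {}
        self.utr5: dict[str, list[GenomeInterval]] = {}
        for t in transcripts:
            if t.cds and "protein_coding" in (t.biotype, t.gene_biotype):
                if genome is not None and not self._canonical(t, genome):
                    continue
                chain = tuple((c.chrom, c.start, c.end, c.strand)
                              for c in t.cds)
                self.cds_chains[chain] = t.id
                for c in t.cds:
                    self._tree(c.chrom).addi(c.start, c.end, t.id)
                lo, hi = t.cds_transcript_range()
                if hi < t.length:
                    self.utr3[t.id] = t.interval_chain(hi, t.length)
                if lo > 0:
                    self.utr5[t.id] = t.interval_chain(0, lo)
        for chain in (cds_sources or []):
            for c in chain:
                self._tree(c.chrom).addi(c.start, c.end, "external")

    def _tree(self, chrom: str) -> IntervalTree:
        return self.cds_tree.setdefault(chrom, IntervalTree())

    @staticmethod
    def _canonical(t: TranscriptModel, genome: dict[str, str]) -> bool:
        """CDS starts at the most upstream in-frame AUG for its stop."""
        seq = t.spliced_sequence(genome)
        lo, hi = t.cds_transcript_range()
        if seq[lo:lo + 3] != "ATG":
            return False
        for i in range(lo - 3, -1, -3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                return True
            if codon == "ATG":
                return False
        return True

    def cds_overlap_bp(self, orf: ORFRecord) -> int:
        total = 0
        tree = self.cds_tree.get(orf.chrom)
        if tree is None:
            return 0
        positions = orf.genomic_positions()
        covered = set()
        for iv in orf.genomic_intervals:
            for hit in tree.overlap(iv.start, iv.end):
                covered |= set(range(hit.begin, hit.end)) & positions
        return len(covered)

    def contained_in_cds(self, orf: ORFRecord) -> bool:
        tree = self.cds_tree.get(orf.chrom)
        if tree is None:
            return False
        covered = set()
        for iv in orf.genomic_intervals:
            for hit in tree.overlap(iv.start, iv.end):
                covered |= set(range(hit.begin, hit.end))
        return orf.genomic_positions() <= covered

    @staticmethod
    def _within(orf: ORFRecord, chains: dict[str, list[GenomeInterval]]
                ) -> bool:
        pos = orf.genomic_positions()
        for chain in chains.values():
            if chain and chain[0].chrom == orf.chrom:
                covered = {p for iv in chain for p in range(iv.start, iv.end)}
                if pos <= covered:
                    return True
        return False

    def utr_overlap(self, orf: ORFRecord) -> bool:
        pos = orf.genomic_positions()
        for chains in (self.utr3, self.utr5):
            for chain in chains.values():
                if chain and chain[0].chrom == orf.chrom:
                    covered = {p for iv in chain
                               for p in range(iv.start, iv.end)}
                    if pos & covered:
                        return True
        return False


def _member_category(t: TranscriptModel) -> str:
    """Provisional category implied by a single member transcript's biotype
    (only the rules that depend on the transcript alone)."""
    bt, gbt = t.biotype, t.gene_biotype or t.biotype
    if "pseudogene" in bt or "pseudogene" in gbt:
        return "pseudogene"
    if bt in NCRNA_BIOTYPES:
        return "ncRNA"
    if bt == "lincRNA" and gbt == "lincRNA":
        return "lincRNA"
    if gbt == "protein_coding":
        return "other"
    if bt in ("sense_overlapping", "nonsense_mediated_decay",
              "retained_intron"):
        return "other"
    return "other"


def classify(orf: ORFRecord, index: AnnotationIndex) -> str:
    """Assign the first matching category in the fixed order, then apply the
    contained-in-CDS re-assignment."""
    members = [index.transcripts[tid] for tid in orf.transcript_ids
               if tid in index.transcripts]
    # annotated: exact CDS chain match of a canonical coding transcript
    if orf.chain_key in index.cds_chains:
        return "annotated"
    member_cats = [_member_category(t) for t in members]
    if "pseudogene" in member_cats:
        return "pseudogene"
    if "ncRNA" in member_cats:
        return "ncRNA"
    category = None
    cds_bp = index.cds_overlap_bp(orf)
    if cds_bp == 0 and index._within(orf, index.utr3):
        category = "utr3"
    elif cds_bp == 0 and index._within(orf, index.utr5):
        category = "utr5"
    elif cds_bp > 0 or index.utr_overlap(orf):
        category = "cds_overlap"
    elif "other" in member_cats:
        category = "other"
    elif "lincRNA" in member_cats:
        category = "lincRNA"
    else:
        log.warning("ORF %s on unknown biotype; classified 'other'", orf.id)
        category = "other"
    if category not in ("annotated", "pseudogene", "ncRNA") \
            and index.contained_in_cds(orf):
        category = "other" if "other" in member_cats else "cds_overlap"
    return category


def classify_all(orfs: list[ORFRecord], index: AnnotationIndex
                 ) -> list[ORFRecord]:
    for orf in orfs:
        orf.category = classify(orf, index)
    return orfs


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def orfs_to_bed12(orfs: list[ORFRecord], path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            ivs = orf.genomic_intervals
            start, end = ivs[0].start, ivs[-1].end
            sizes = ",".join(str(len(iv)) for iv in ivs)
            offsets = ",".join(str(iv.start - start) for iv in ivs)
            fh.write("\t".join([
                orf.chrom, str(start), str(end), orf.id, "0", orf.strand,
                str(start), str(end), "0", str(len(ivs)), sizes, offsets,
            ]) + "\n")


def orfs_to_table(orfs: list[ORFRecord]):
    import pandas as pd
    return pd.DataFrame([{
        "orf_id": o.id,
        "transcript_ids": ",".join(o.transcript_ids),
        "chrom": o.chrom,
        "start": o.genomic_intervals[0].start,
        "end": o.genomic_intervals[-1].end,
        "strand": o.strand,
        "n_codons": o.n_codons,
        "category": o.category,
        "nt_seq": o.nt_seq,
        "aa_seq": o.aa_seq,
    } for o in orfs])
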