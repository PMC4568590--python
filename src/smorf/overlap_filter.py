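"""Two-pass overlap filter for predicted sORFs.

Step 1 keeps annotated sORFs and predictions that do not intersect
frame-conserved annotated coding exons.  Step 2 removes predictions
contained in a longer SVM-predicted ORF that itself passed step 1; within a
containment family the longest ORF (ties broken by best selection score) is
retained as the representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import GenomeInterval
from .orf_catalog import ORFRecord


@dataclass
class ConservedExonSet:
    """Annotated coding exons whose reading frame is conserved in at least
    ``threshold`` species (frame-conservation counts as in the classifier
    features)."""

    threshold: int
    exons: list[GenomeInterval] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def add(self, exon: GenomeInterval) -> None:
        self.exons.append(exon)
        self._trees.setdefault(exon.chrom, IntervalTree()).addi(
            exon.start, exon.end, exon)

    def intersects(self, orf: ORFRecord, same_strand: bool = False) -> bool:
        tree = self._trees.get(orf.chrom)
        if tree is None:
            return False
        for iv in orf.genomic_intervals:
            for hit in tree.overlap(iv.start, iv.end):
                if not same_strand or hit.data.strand in (".", iv.strand):
                    return True
        return False


def build_conserved_exons(exons: list[GenomeInterval],
                          counts: list[int],
                          threshold: int) -> ConservedExonSet:
    """Retain exons whose frame-conservation species count reaches the
    threshold (for example 11 species for human, 2 for worm, or a value
    derived from the minimum-average-error ROC point)."""
    out = ConservedExonSet(threshold=threshold)
    for exon, count in zip(exons, counts):
        if count >= threshold:
            out.add(exon)
    return out


def _contained_in(a: ORFRecord, b: ORFRecord, same_strand: bool = True) -> bool:
    """Genomic interval-chain containment: every base of a lies in b."""
    if a.chrom != b.chrom:
        return False
    if same_strand and a.strand != b.strand:
        return False
    return a.genomic_positions() < b.genomic_positions() or (
        a.genomic_positions() == b.genomic_positions()
        and len(a.nt_seq) < len(b.nt_seq))


def apply_overlap_filter(predicted: list[ORFRecord],
                         conserved_exons: ConservedExonSet,
                         all_predicted_with_scores: list[ORFRecord]
                         | None = None,
                         same_strand_step2: bool = True
                         ) -> tuple[list[ORFRecord], dict[str, str]]:
    """Apply both passes; returns (kept ORFs, rejection reason per ORF id).

    ``predicted`` are the ORFs to filter (annotated ones always pass step
    1); ``all_predicted_with_scores`` defaults to ``predicted`` and is the
    pool of SVM-predicted ORFs that can shadow a contained prediction.
    """
    pool = all_predicted_with_scores or predicted
    reasons: dict[str, str] = {}
    # step 1: conserved-coding-exon overlap
    step1 = []
    step1_ids = set()
    for orf in predicted:
        if orf.category != "annotated" and conserved_exons.intersects(orf):
            reasons[orf.id] = "conserved_exon_overlap"
        else:
            step1.append(orf)
            step1_ids.add(orf.id)
    pool_step1 = [o for o in pool
                  if o.category == "annotated"
                  or not conserved_exons.intersects(o)]
    # step 2: containment in a longer step-1-passing prediction
    def rank(o: ORFRecord) -> tuple:
        return (len(o.nt_seq), o.selection_score or 0.0)

    kept = []
    for orf in step1:
        shadows = [b for b in pool_step1
                   if b.id != orf.id
                   and _contained_in(orf, b, same_strand=same_strand_step2)]
        if shadows and orf.category != "annotated":
            best = max(shadows, key=rank)
            reasons[orf.id] = f"contained_in_longer:{best.id}"
        else:
            kept.append(orf)
    return kept, reasons
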