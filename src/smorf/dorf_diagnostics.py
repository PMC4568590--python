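"""Diagnostics for 3'UTR sORFs (dORFs): do they look like stop-codon
readthrough or unannotated terminal exons, or like independent ORFs?

All coordinates are spliced transcript coordinates.  The conservation step
at a stop codon is mean(25 nt inside) - mean(25 nt outside); the stop codon
itself is excluded from both windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ConservationTrack, GenomeInterval, TranscriptModel
from .orf_catalog import ORFRecord, STOP_CODONS

STEP_WINDOW = 25


@dataclass
class DorfStats:
    orf_id: str
    stop_step: float
    distance_to_cds_stop: int
    frame_offset: int            # dORF start frame relative to upstream CDS
    n_intervening_stops: int
    overlaps_annotated_cds: bool
    step_flagged: bool = False   # a step window was truncated


def _transcript_track(t: TranscriptModel, track: ConservationTrack
                      ) -> np.ndarray:
    return np.array([track.score(t.chrom, g) for g in t.genomic_positions()])


def stop_step(track_values: np.ndarray, boundary: int,
              window: int = STEP_WINDOW) -> tuple[float, bool]:
    """Step in conservation at a codon boundary: mean over ``window`` nt
    ending at ``boundary`` minus mean over ``window`` nt starting there.
    Returns (step, truncated_flag); truncated windows use what is
    available."""
    inside = track_values[max(0, boundary - window):boundary]
    outside = track_values[boundary:boundary + window]
    flagged = len(inside) < window or len(outside) < window
    if len(inside) == 0 or len(outside) == 0:
        return float("nan"), True
    return float(inside.mean() - outside.mean()), flagged


def cds_stop_step(transcript: TranscriptModel, track: ConservationTrack
                  ) -> tuple[float, bool]:
    """Conservation step at the annotated CDS stop codon: 25 nt of coding
    sequence upstream of the stop codon vs. 25 nt of 3'UTR downstream of
    it (the stop codon itself in neither window)."""
    rng = transcript.cds_transcript_range()
    if rng is None:
        raise ValueError(f"{transcript.id} has no annotated CDS")
    values = _transcript_track(transcript, track)
    lo, hi = rng
    inside = values[max(0, hi - 3 - STEP_WINDOW):hi - 3]
    outside = values[hi:hi + STEP_WINDOW]
    flagged = len(inside) < STEP_WINDOW or len(outside) < STEP_WINDOW
    if len(inside) == 0 or len(outside) == 0:
        return float("nan"), True
    return float(inside.mean() - outside.mean()), flagged


def dorf_start_step(dorf: ORFRecord, transcript: TranscriptModel,
                    track: ConservationTrack) -> tuple[float, bool]:
    """Conservation step at the dORF start codon (outside = 25 nt upstream
    of the AUG, inside = first 25 nt of the dORF)."""
    values = _transcript_track(transcript, track)
    s = dorf.transcript_start
    outside = values[max(0, s - STEP_WINDOW):s]
    inside = values[s:s + STEP_WINDOW]
    flagged = len(inside) < STEP_WINDOW or len(outside) < STEP_WINDOW
    if len(inside) == 0 or len(outside) == 0:
        return float("nan"), True
    return float(inside.mean() - outside.mean()), flagged


def dorf_stats(dorf: ORFRecord, transcript: TranscriptModel,
               track: ConservationTrack, genome: dict[str, str],
               cds_index=None) -> DorfStats:
    """Full readthrough/terminal-exon diagnostics for one dORF on its host
    transcript.  ``cds_index`` is an AnnotationIndex-like object exposing
    ``cds_overlap_bp`` (for the overlap-with-annotated-CDS flag)."""
    rng = transcript.cds_transcript_range()
    if rng is None:
        raise ValueError(f"{transcript.id} has no annotated CDS")
    cds_lo, cds_hi = rng
    if dorf.transcript_start < cds_hi:
        raise ValueError(f"{dorf.id} is not downstream of the CDS stop")
    step, flagged = cds_stop_step(transcript, track)
    distance = dorf.transcript_start - cds_hi
    frame_offset = (dorf.transcript_start - cds_lo) % 3
    seq = transcript.spliced_sequence(genome)
    n_stops = 0
    for i in range(cds_hi, dorf.transcript_start - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            n_stops += 1
    overlaps = bool(cds_index is not None
                    and cds_index.cds_overlap_bp(dorf) > 0)
    return DorfStats(orf_id=dorf.id, stop_step=step,
                     distance_to_cds_stop=distance,
                     frame_offset=frame_offset,
                     n_intervening_stops=n_stops,
                     overlaps_annotated_cds=overlaps,
                     step_flagged=flagged)


def match_readthrough(candidate_stops: list[GenomeInterval],
                      published_stops: list[GenomeInterval]
                      ) -> list[GenomeInterval]:
    """Exact genomic stop-codon coordinate matches between candidate 3'UTR
    sORF host stops and a published readthrough stop list."""
    published = {(s.chrom, s.start, s.end) for s in published_stops}
    return [s for s in candidate_stops
            if (s.chrom, s.start, s.end) in published]
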