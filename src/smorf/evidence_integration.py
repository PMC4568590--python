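"""Translation and expression evidence for predicted sORFs.

Translation calling uses the ORFscore: ribosome-protected-fragment 5' ends,
offset-corrected per read length from a metagene analysis around annotated
CDS starts, are tallied per codon position; actively translated ORFs show a
strong excess in frame with the start codon.  Expression evidence is TPM
and a tissue/stage specificity information content per transcript.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameCounts:
    """5' read ends per codon position across an ORF, start and stop codons
    excluded; F1 is the position in frame with the start codon."""

    F1: int
    F2: int
    F3: int

    def __post_init__(self):
        if min(self.F1, self.F2, self.F3) < 0:
            raise ValueError("negative frame count")


def orfscore(counts: FrameCounts) -> float:
    """Signed log2 chi-square-like deviation of the three frame counts from
    uniformity; negative when frame 2 or 3 dominates, 0 for no reads."""
    total = counts.F1 + counts.F2 + counts.F3
    if total == 0:
        return 0.0
    mean = total / 3.0
    dev = sum((f - mean) ** 2 / mean
              for f in (counts.F1, counts.F2, counts.F3))
    score = math.log2(dev + 1.0)
    if counts.F2 > counts.F1 or counts.F3 > counts.F1:
        return -score
    return score


def frame_counts(read_positions, orf_start: int, orf_end: int,
                 exclude_boundary_codons: bool = True) -> FrameCounts:
    """Tally 5' ends (transcript coordinates, already offset-corrected)
    falling in the ORF, per codon position.  Reads in the first and last
    codon are excluded by default."""
    lo = orf_start + (3 if exclude_boundary_codons else 0)
    hi = orf_end - (3 if exclude_boundary_codons else 0)
    f = [0, 0, 0]
    for p in read_positions:
        if lo <= p < hi:
            f[(p - orf_start) % 3] += 1
    return FrameCounts(*f)


def metagene_offsets(reads: pd.DataFrame, cds_starts: dict[str, int],
                     window: int = 100, min_reads: int = 100
                     ) -> dict[int, tuple[int, float]]:
    """Per read length, the 5' offset of the P-site and the phasing
    fraction, from 5' read ends aggregated around annotated CDS starts.

    The absolute offset is the position of the initiation peak upstream of
    the start codon (the strongest 5'-end pile-up at ``start - offset``);
    phasing alone identifies it only mod 3.  The phasing fraction is the
    proportion of corrected ends in frame with the start.  ``reads`` needs
    columns transcript, position (5' end, transcript coordinates), length;
    lengths with fewer than ``min_reads`` reads near a start are skipped.
    """
    out: dict[int, tuple[int, float]] = {}
    near = []
    for row in reads.itertuples(index=False):
        start = cds_starts.get(row.transcript)
        if start is None:
            continue
        rel = row.position - start
        if -window <= rel < window:
            near.append((int(row.length), rel))
    by_length: dict[int, list[int]] = {}
    for length, rel in near:
        by_length.setdefault(length, []).append(rel)
    for length, rels in sorted(by_length.items()):
        if len(rels) < min_reads:
            log.info("read length %d skipped (%d reads < %d)",
                     length, len(rels), min_reads)
            continue
        rels = np.array(rels)
        upstream = rels[(rels < 0) & (rels >= -length)]
        if upstream.size:
            offsets, counts = np.unique(-upstream, return_counts=True)
            best_off = int(offsets[np.argmax(counts)])
        else:  # no initiation signal: frame-maximizing offset (mod 3)
            best_off = int(max(range(3), key=lambda o: float(
                ((rels + o) % 3 == 0).mean())))
        frac = float(((rels + best_off) % 3 == 0).mean())
        out[length] = (best_off, frac)
    return out


def dataset_quality(pos_scores, neg_scores,
                    d_min: float = 0.55) -> tuple[float, bool]:
    """Two-sample Kolmogorov-Smirnov D between ORFscores of annotated sORFs
    and the negative control; the dataset passes iff D >= d_min."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty score group")
    d = float(stats.ks_2samp(pos, neg).statistic)
    return d, d >= d_min


def call_translated(scores, cutoff: float = 6.0) -> np.ndarray:
    """ORFscore >= cutoff calls an ORF translated."""
    return np.asarray(scores, float) >= cutoff


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def fpkm_to_tpm(fpkm: pd.DataFrame, min_fpkm: float = 1e-4) -> pd.DataFrame:
    """Convert an FPKM matrix (transcripts x samples) to TPM per sample:
    TPM = 1e6 * FPKM / sum(FPKM).  Transcripts with all FPKM below
    ``min_fpkm`` are dropped first."""
    keep = (fpkm >= min_fpkm).any(axis=1)
    kept = fpkm.loc[keep]
    return 1e6 * kept / kept.sum(axis=0)


def specificity_ic(tpm_row: np.ndarray) -> float:
    """Tissue/stage specificity as normalized information content over
    r_t = log2(TPM_t + 1) / sum_s log2(TPM_s + 1):
    IC = (1/log2 N) * sum_t r_t * log2(r_t * N).  0 = uniform use of all
    samples, 1 = expression confined to a single sample."""
    tpm = np.asarray(tpm_row, float)
    n = tpm.size
    if n < 2:
        return float("nan")
    lt = np.log2(tpm + 1.0)
    total = lt.sum()
    if total == 0:
        return float("nan")
    r = lt / total
    terms = np.where(r > 0, r * np.log2(np.where(r > 0, r, 1.0) * n), 0.0)
    return float(terms.sum() / math.log2(n))


def expression_metrics(fpkm: pd.DataFrame,
                       min_fpkm: float = 1e-4) -> pd.DataFrame:
    """Mean TPM (averaged over samples with non-zero TPM) and specificity
    IC per transcript."""
    tpm = fpkm_to_tpm(fpkm, min_fpkm=min_fpkm)
    records = []
    for tid, row in tpm.iterrows():
        vals = row.to_numpy(float)
        nonzero = vals[vals > 0]
        records.append({
            "transcript": tid,
            "mean_tpm": float(nonzero.mean()) if nonzero.size else 0.0,
            "ic": specificity_ic(vals),
        })
    return pd.DataFrame(records).set_index("transcript")
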