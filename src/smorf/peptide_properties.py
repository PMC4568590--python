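"""Peptide-level sequence properties: amino-acid/codon usage profiles and
their clustering, per-amino-acid codon bias, linear-motif scanning in
disordered regions, and filtering of supplied proteome-homology hits.

Disorder values and proteome hits are consumed as inputs (per-residue TSV
and blast-style tables); this module implements only the analyses on top.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS_PER_AA: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    CODONS_PER_AA.setdefault(aa, []).append(codon)


@dataclass
class UsageProfile:
    """Amino-acid frequencies (start and stop excluded) and per-amino-acid
    codon counts for a group of ORFs."""

    aa_freq: np.ndarray                 # 20-dim, sums to 1
    codon_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_orfs(cls, nt_seqs: list[str]) -> "UsageProfile":
        aa_counts = dict.fromkeys(AMINO_ACIDS, 0)
        codon_counts: dict[str, dict[str, int]] = {}
        for nt in nt_seqs:
            # exclude start codon and stop codon
            for i in range(3, len(nt) - 3, 3):
                codon = nt[i:i + 3].upper()
                aa = CODON_TABLE.get(codon)
                if aa is None:
                    continue
                aa_counts[aa] += 1
                codon_counts.setdefault(aa, dict.fromkeys(
                    CODONS_PER_AA[aa], 0))[codon] += 1
        total = sum(aa_counts.values())
        freq = np.array([aa_counts[a] / total if total else 0.0
                         for a in AMINO_ACIDS])
        return cls(aa_freq=freq, codon_counts=codon_counts)


def codon_bias_kl(profile: UsageProfile) -> dict[str, float | None]:
    """Kullback-Leibler divergence (bits) of the observed codon distribution
    per amino acid from the uniform one; single-codon amino acids give 0,
    unobserved ones None."""
    out: dict[str, float | None] = {}
    for aa in AMINO_ACIDS:
        codons = CODONS_PER_AA[aa]
        counts = profile.codon_counts.get(aa)
        total = sum(counts.values()) if counts else 0
        if total == 0:
            out[aa] = None
            continue
        if len(codons) == 1:
            out[aa] = 0.0
            continue
        kl = 0.0
        for c in codons:
            p = counts[c] / total
            if p > 0:
                kl += p * math.log2(p * len(codons))
        out[aa] = kl
    return out


def usage_clustering(group_profiles: dict[str, np.ndarray],
                     group_members: dict[str, list[np.ndarray]] | None = None,
                     runs: int = 100, seed: int = 0):
    """Hierarchical clustering (correlation metric, average linkage) of
    group usage profiles plus a resampling stability estimate.

    ``group_members`` optionally maps group -> per-ORF frequency vectors;
    each resampling run keeps every ORF with probability 0.5, recomputes the
    group profiles, and checks whether the full-data 2-cluster split is
    reproduced.  Returns (linkage matrix, group order, stability)."""
    names = sorted(group_profiles)
    if len(names) < 3:
        raise ValueError("need at least 3 groups to cluster")
    X = np.vstack([group_profiles[n] for n in names])
    Z = average(pdist(X, metric="correlation"))
    ref_split = fcluster(Z, t=2, criterion="maxclust")
    stability = None
    if group_members is not None:
        rng = np.random.default_rng(seed)
        same = 0
        for _ in range(runs):
            rows = []
            for n in names:
                members = group_members[n]
                keep = [m for m in members if rng.random() < 0.5]
                if not keep:
                    keep = [members[rng.integers(len(members))]]
                rows.append(np.mean(keep, axis=0))
            Zr = average(pdist(np.vstack(rows), metric="correlation"))
            split = fcluster(Zr, t=2, criterion="maxclust")
            if _same_partition(ref_split, split):
                same += 1
        stability = same / runs
    return Z, names, stability


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return ((a == a[0]) == (b == b[0])).all()


@dataclass(frozen=True)
class MotifMatch:
    pattern: str
    start: int
    end: int
    mean_disorder: float


def motif_scan(aa_seq: str, disorder_values, motif_patterns: dict[str, str],
               disorder_threshold: float = 0.5
               ) -> tuple[list[MotifMatch], float]:
    """Scan a peptide for regular-expression motifs and keep matches whose
    span has mean disorder strictly above the threshold.  Returns the
    matches and the per-residue motif density."""
    disorder = np.asarray(disorder_values, dtype=float)
    if len(disorder) != len(aa_seq):
        raise ValueError(
            f"disorder length {len(disorder)} != peptide length"
            f" {len(aa_seq)}")
    matches = []
    for name, pattern in motif_patterns.items():
        for m in re.finditer(pattern, aa_seq):
            span = disorder[m.start():m.end()]
            if span.size and float(span.mean()) > disorder_threshold:
                matches.append(MotifMatch(name, m.start(), m.end(),
                                          float(span.mean())))
    density = len(matches) / len(aa_seq) if aa_seq else 0.0
    return matches, density


BAD_SUBJECT_FLAGS = ("PREDICTED", "hypothetical", "unknown",
                     "uncharacterized", "putative")


@dataclass(frozen=True)
class ProteomeHit:
    query_id: str
    subject_id: str
    subject_description: str
    percent_identity: float
    e_value: float
    query_coverage: float          # fraction of query aligned, in [0, 1]
    query_length: int
    subject_length: int


def filter_proteome_hits(hits: list[ProteomeHit],
                         e_max: float = 1e-5,
                         min_identity: float = 50.0,
                         min_coverage: float = 0.8,
                         evalue_direction: str = "below"
                         ) -> dict[str, ProteomeHit]:
    """Best credible proteome hit per query: E-value below threshold
    (``evalue_direction='above'`` flips the comparison), identity > 50,
    query coverage > 80 %, subject at least query length, and no dubious
    annotation flags; best by percent identity."""
    best: dict[str, ProteomeHit] = {}
    for h in hits:
        if evalue_direction == "below":
            if h.e_value >= e_max:
                continue
        elif h.e_value <= e_max:
            continue
        if h.percent_identity <= min_identity:
            continue
        if h.query_coverage <= min_coverage:
            continue
        if h.subject_length < h.query_length:
            continue
        desc = h.subject_description
        if any(flag.lower() in desc.lower() for flag in BAD_SUBJECT_FLAGS):
            continue
        cur = best.get(h.query_id)
        if cur is None or h.percent_identity > cur.percent_identity:
            best[h.query_id] = h
    return best


def read_elm_classes(path) -> dict[str, str]:
    """Read motif patterns from an ELM-classes style TSV (identifier and
    regular-expression columns)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    name_col = cols.get("elmidentifier") or df.columns[0]
    pat_col = cols.get("regex") or cols.get("pattern") or df.columns[-1]
    return dict(zip(df[name_col], df[pat_col]))


def read_disorder(path) -> dict[str, np.ndarray]:
    """Read per-residue disorder values from a TSV with columns
    (orf_id, position, disorder)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    out = {}
    for orf_id, grp in df.groupby(df.columns[0]):
        out[orf_id] = grp.sort_values(df.columns[1])[
            df.columns[2]].to_numpy(float)
    return out
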