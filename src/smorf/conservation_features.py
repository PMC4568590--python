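"""Alignment-derived conservation features for candidate sORFs.

Four features feed the downstream classifier: a codon-level selection score
(a plug-in slot for PhyloCSF output, with a built-in log-odds surrogate),
the number of species that conserve the reading frame, and the Euclidean
distances of the phastCons-style profiles around start and stop codons from
the positive-set mean.  The module also infers, per ORF, the most recent
common ancestor of the species conserving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import AlignmentBlock, ConservationTrack, TranscriptModel
from .orf_catalog import ORFRecord, STOP_CODONS

WINDOW = 50  # nt, centered on the first base of the start / stop codon

# Default codon-event log-odds tables for the surrogate selection score:
# probabilities of observing an (identical, synonymous, nonsynonymous,
# stop-introducing) species codon under coding-like vs. neutral evolution.
# These are package defaults chosen to separate coding-like from neutral
# fixtures; real analyses should supply precomputed PhyloCSF scores via
# backend="table".
P_CODING = {"identical": 0.55, "synonymous": 0.30,
            "nonsynonymous": 0.14, "stop": 0.01}
P_NEUTRAL = {"identical": 0.40, "synonymous": 0.20,
             "nonsynonymous": 0.35, "stop": 0.05}


@dataclass
class SpeciesFlags:
    coverage_fraction: float = 0.0
    has_frameshift_indel: bool = False
    has_premature_stop: bool = False
    start_conserved: bool = False
    stop_conserved: bool = False
    splice_sites_conserved: bool = True


@dataclass
class StitchedAlignment:
    """Per-species rows restricted to an ORF, in transcript orientation.

    Row characters: a base, '-' (species gap at an aligned reference base),
    or '.' (reference base not covered by any alignment block for that
    species).  Insertions relative to the reference are tracked separately.
    """

    orf_id: str
    ref_seq: str
    ref_species: str
    rows: dict[str, str]
    insertions: dict[str, list[int]]
    flags: dict[str, SpeciesFlags] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return [s for s in self.rows if s != self.ref_species]


@dataclass
class FeatureVector:
    orf_id: str
    selection_score: float
    n_frame_conserved_species: int
    start_profile_dist: float
    stop_profile_dist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.selection_score,
                         self.n_frame_conserved_species,
                         self.start_profile_dist, self.stop_profile_dist])


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def stitch_and_flag(orf: ORFRecord, blocks: list[AlignmentBlock],
                    ref_species: str = "ref") -> StitchedAlignment:
    """Stitch alignment blocks over the ORF and compute per-species flags.

    Indel flags are derived from the raw blocks (deletion runs over
    reference bases, plus the insertion index) before any stitching could
    mask them; a frameshifting indel is any indel of length != 0 (mod 3).
    """
    species = sorted({sp for b in blocks for sp in b.rows
                      if sp != ref_species})
    # genomic positions of the ORF in ascending order
    g_positions = [p for iv in orf.genomic_intervals
                   for p in range(iv.start, iv.end)]
    pos_index = {p: i for i, p in enumerate(g_positions)}
    L = len(g_positions)
    rows = {sp: ["."] * L for sp in species}
    ins: dict[str, list[int]] = {sp: [] for sp in species}
    for b in blocks:
        lo = max(b.start, g_positions[0])
        hi = min(b.end, g_positions[-1] + 1)
        if lo >= hi:
            continue
        profiles = {sp: b.species_profile(sp) for sp in b.rows
                    if sp != ref_species}
        for p in range(lo, hi):
            i = pos_index.get(p)
            if i is None:
                continue
            for sp, prof in profiles.items():
                rows[sp][i] = prof[p - b.start]
        for sp, anchored in b.insertions.items():
            if sp == ref_species:
                continue
            for anchor, length in anchored.items():
                # insertions strictly inside the ORF's exonic intervals
                if any(iv.start < anchor < iv.end
                       for iv in orf.genomic_intervals):
                    ins[sp].append(length)
    if orf.strand == "-":
        rows = {sp: [c.translate(_COMP) for c in r[::-1]]
                for sp, r in rows.items()}
    stitched_rows = {sp: "".join(r) for sp, r in rows.items()}
    stitched_rows[ref_species] = orf.nt_seq
    stitched = StitchedAlignment(orf_id=orf.id, ref_seq=orf.nt_seq,
                                 ref_species=ref_species, rows=stitched_rows,
                                 insertions=ins)
    for sp in species:
        stitched.flags[sp] = _species_flags(stitched, sp)
    return stitched


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _species_flags(st: StitchedAlignment, sp: str) -> SpeciesFlags:
    row = st.rows[sp]
    L = len(row)
    n_aligned = sum(1 for c in row if c not in "-.")
    flags = SpeciesFlags(coverage_fraction=n_aligned / L if L else 0.0)
    # deletion runs over covered reference bases
    run = 0
    fs = False
    for c in row + ".":
        if c == "-":
            run += 1
        else:
            if run and run % 3:
                fs = True
            run = 0
    if any(length % 3 for length in st.insertions.get(sp, [])):
        fs = True
    flags.has_frameshift_indel = fs
    n_cod = L // 3
    for i in range(n_cod):
        codon = row[3 * i:3 * i + 3]
        if any(c in "-." for c in codon):
            continue
        if i == 0:
            flags.start_conserved = codon.upper() == "ATG"
        elif i == n_cod - 1:
            flags.stop_conserved = codon.upper() in STOP_CODONS
        elif codon.upper() in STOP_CODONS:
            flags.has_premature_stop = True
    return flags


def splice_site_conservation(orf: ORFRecord, blocks: list[AlignmentBlock],
                             ref_species: str = "ref") -> dict[str, bool]:
    """Per species: are all donor/acceptor dinucleotides flanking the ORF's
    introns identical to the reference row?  Single-exon ORFs map to True;
    uncovered splice sites count as not conserved."""
    species = sorted({sp for b in blocks for sp in b.rows
                      if sp != ref_species})
    result = {sp: True for sp in species}
    ivs = orf.genomic_intervals
    site_positions = []
    for up, down in zip(ivs, ivs[1:]):
        site_positions += [up.end, up.end + 1, down.start - 2, down.start - 1]
    for pos in site_positions:
        ref_base, bases = None, {}
        for b in blocks:
            if b.start <= pos < b.end:
                ref_base = b.species_profile(b.ref_species)[pos - b.start] \
                    if b.ref_species in b.rows else None
                # reference profile: reconstruct from ref row directly
                ref_base = _ref_base(b, pos)
                for sp in species:
                    if sp in b.rows:
                        bases[sp] = b.species_profile(sp)[pos - b.start]
                break
        for sp in species:
            base = bases.get(sp, ".")
            if ref_base is None or base in "-." or base.upper() != ref_base:
                result[sp] = False
    return result


def _ref_base(block: AlignmentBlock, pos: int) -> str | None:
    coord = block.start
    for c in block.ref_row:
        if c != "-":
            if coord == pos:
                return c.upper()
            coord += 1
    return None


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def frame_conservation_count(stitched: StitchedAlignment,
                             min_coverage: float = 0.5) -> int:
    """Number of non-reference species with >= 50 % coverage over the ORF
    and no frameshifting indels."""
    return sum(1 for sp in stitched.species
               if stitched.flags[sp].coverage_fraction >= min_coverage
               and not stitched.flags[sp].has_frameshift_indel)


def selection_score(stitched: StitchedAlignment,
                    backend: str = "surrogate",
                    score_table: dict[str, float] | None = None,
                    p_coding: dict[str, float] = P_CODING,
                    p_neutral: dict[str, float] = P_NEUTRAL,
                    min_coverage: float = 0.5) -> float:
    """Codon-level selection score for one stitched ORF alignment.

    backend="table" looks the ORF up in precomputed scores (the supported
    path for real PhyloCSF output).  backend="surrogate" sums, over species
    with sufficient coverage and intact frame and over gap-free codon
    columns, log2 odds of the observed codon event (identical, synonymous,
    nonsynonymous, or stop-introducing) under coding vs. neutral evolution.
    """
    if backend == "table":
        if score_table is None or stitched.orf_id not in score_table:
            missing = [stitched.orf_id]
            raise KeyError(f"no precomputed score for ORFs: {missing}")
        return float(score_table[stitched.orf_id])
    if backend != "surrogate":
        raise ValueError(f"unknown backend {backend!r}")
    total = 0.0
    ref = stitched.ref_seq
    n_cod = len(ref) // 3
    for sp in stitched.species:
        fl = stitched.flags[sp]
        if fl.coverage_fraction < min_coverage or fl.has_frameshift_indel:
            continue
        row = stitched.rows[sp]
        for i in range(n_cod):
            codon = row[3 * i:3 * i + 3].upper()
            if any(c in "-.N" for c in codon):
                continue
            event = classify_codon_event(ref[3 * i:3 * i + 3], codon)
            total += math.log2(p_coding[event] / p_neutral[event])
    return total


def classify_codon_event(ref_codon: str, sp_codon: str) -> str:
    if sp_codon == ref_codon:
        return "identical"
    if sp_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        return "stop"
    if ref_codon in STOP_CODONS:
        return "identical" if sp_codon in STOP_CODONS else "nonsynonymous"
    if str(Seq(sp_codon).translate()) == str(Seq(ref_codon).translate()):
        return "synonymous"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# conservation step profiles
# ---------------------------------------------------------------------------

def orf_step_profiles(orf: ORFRecord, transcript: TranscriptModel,
                      track: ConservationTrack,
                      chrom_length: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-base conservation in 50-nt windows centered on the first base of
    the start and stop codons, in spliced transcript coordinates, extended
    into flanking genomic sequence past the transcript ends.  Positions off
    the chromosome are NaN."""
    start_anchor = orf.transcript_start
    stop_anchor = orf.transcript_end - 3
    return (_window_profile(transcript, track, start_anchor, chrom_length),
            _window_profile(transcript, track, stop_anchor, chrom_length))


def _window_profile(t: TranscriptModel, track: ConservationTrack,
                    anchor: int, chrom_length: int | None) -> np.ndarray:
    half = WINDOW // 2
    sign = -1 if t.strand == "-" else 1
    g_first = t.to_genomic(0)
    g_last = t.to_genomic(t.length - 1)
    out = np.full(WINDOW, np.nan)
    for k, t_pos in enumerate(range(anchor - half, anchor + half)):
        if 0 <= t_pos < t.length:
            g = t.to_genomic(t_pos)
        elif t_pos < 0:
            g = g_first + sign * t_pos
        else:
            g = g_last + sign * (t_pos - (t.length - 1))
        if g < 0 or (chrom_length is not None and g >= chrom_length):
            continue
        out[k] = track.score(t.chrom, g)
    return out


def build_mean_profile(profiles: list[np.ndarray]) -> np.ndarray:
    """Base-wise average over the positive training set."""
    if not profiles:
        raise ValueError("no profiles to average")
    return np.nanmean(np.vstack(profiles), axis=0)


def step_profile_distance(profile: np.ndarray,
                          mean_profile: np.ndarray) -> float:
    """Euclidean distance between an ORF profile and the positive-set mean,
    scaled to a 50-base equivalent when the window was clipped."""
    valid = ~np.isnan(profile) & ~np.isnan(mean_profile)
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    sq = float(np.sum((profile[valid] - mean_profile[valid]) ** 2))
    return math.sqrt(sq * WINDOW / n)


# ---------------------------------------------------------------------------
# ancestral conservation
# ---------------------------------------------------------------------------

def conserving_species(stitched: StitchedAlignment,
                       splice_ok: dict[str, bool] | None = None) -> set[str]:
    """Species where start and stop codons (and, if applicable, splice
    sites) are conserved and premature stops and frameshifting indels are
    absent.  The reference is always included."""
    out = {stitched.ref_species}
    for sp in stitched.species:
        fl = stitched.flags[sp]
        if (fl.start_conserved and fl.stop_conserved
                and not fl.has_premature_stop
                and not fl.has_frameshift_indel
                and (splice_ok is None or splice_ok.get(sp, False))):
            out.add(sp)
    return out


def mrca_of_set(tree, species: set[str], ref_species: str):
    """MRCA clade of a conserving species set (the reference leaf itself
    when nothing but the reference conserves)."""
    leaves = {l.name for l in tree.get_terminals()}
    unknown = species - leaves
    if unknown:
        raise ValueError(f"species absent from tree: {sorted(unknown)}")
    if species == {ref_species}:
        return next(l for l in tree.get_terminals() if l.name == ref_species)
    return tree.common_ancestor(sorted(species))


def mrca_conservation(species_sets: list[set[str]], tree,
                      ref_species: str) -> list[tuple[str, float]]:
    """For each ancestor on the root-to-reference path, the fraction of ORFs
    whose conserving-set MRCA is at least that old.  Returned youngest
    (the reference leaf) to oldest (the root)."""
    ref_leaf = next(l for l in tree.get_terminals() if l.name == ref_species)
    path = [tree.root] + tree.get_path(ref_leaf)  # root ... leaf
    depth = {id(c): i for i, c in enumerate(path)}
    mrca_depths = []
    for s in species_sets:
        clade = mrca_of_set(tree, s, ref_species)
        mrca_depths.append(depth[id(clade)])
    n = len(species_sets)
    out = []
    for i, clade in enumerate(reversed(path)):  # youngest -> oldest
        d = depth[id(clade)]
        frac = sum(1 for m in mrca_depths if m <= d) / n if n else 0.0
        label = clade.name or f"ancestor_{len(path) - 1 - i}"
        out.append((label, frac))
    return out
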