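"""Synthetic fixture generator with known ground truth.

Emulates every input the pipeline consumes — genome FASTA, GTF annotation,
multiple-species alignment (MAF), conservation track (bedGraph), SNPs
(VCF), ribosome-profiling 5' ends (BED), and an FPKM expression table —
for loci of three declared classes:

* ``coding``      — sORFs under purifying selection: synonymous-biased
                    codon substitution, conserved frame and boundaries, and
                    a conservation-track step at start and stop;
* ``neutral``     — frame-agnostic nucleotide substitution with frequent
                    frameshifting indels and a flat track;
* ``pseudogene``  — coding-derived but hit by nonsense/frameshift events,
                    without track steps.

Substitutions are simulated per branch of the species tree with a simple
two-rate (synonymous/nonsynonymous) codon model and no rate heterogeneity
across sites; the reference leaf stays identical to the simulated genome.
Truth tables record class, true omega, true frame bias, planted homology
families, and true expression specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (AlignmentBlock, ConservationTrack, GenomeInterval,
                         TranscriptModel, VariantRecord, write_genome,
                         write_gtf, write_maf, write_variants)
from .orf_catalog import ORFRecord, STOP_CODONS
from .selection_analysis import codon_sites

DEFAULT_TREE = "(((ref:0.10,sp1:0.10):0.08,sp2:0.18):0.10,(sp3:0.25,sp4:0.25):0.08);"

NON_STOP_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - STOP_CODONS - {"ATG"})


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_annotated: int = 30        # coding-like, annotated protein_coding CDS
    n_novel: int = 20            # coding-like, on lincRNAs (novel targets)
    n_neutral_ncrna: int = 30    # neutral, on snoRNAs (negative controls)
    n_neutral_linc: int = 10     # neutral, on lincRNAs
    n_pseudogene: int = 8
    orf_codons: tuple[int, int] = (12, 60)   # start..stop inclusive
    utr_len: int = 60
    spacer_len: int = 150
    tree_newick: str = DEFAULT_TREE
    ref_species: str = "ref"
    # per unit branch length
    syn_rate: float = 0.8        # per codon
    nonsyn_rate: float = 0.12    # per codon
    neutral_rate: float = 1.0    # per nucleotide
    indel_prob: float = 0.5      # per species per neutral/pseudogene locus
    inframe_indel_prob: float = 0.05  # per species per coding locus
    # SNPs
    omega_coding: float = 0.2
    omega_neutral: float = 1.0
    snp_density_per_kb: float = 20.0
    # ribosome profiling
    reads_per_orf: int = 120
    frame_bias: float = 0.8
    read_length: int = 29
    p_site_offset: int = 12
    # expression
    n_samples: int = 8

    def __post_init__(self):
        lo, hi = self.orf_codons
        if lo < 9:
            raise ValueError("ORFs must span at least 27 nt (9 codons)")
        if not 1 / 3 <= self.frame_bias <= 1:
            raise ValueError("frame bias must lie in [1/3, 1]")
        for r in (self.syn_rate, self.nonsyn_rate, self.neutral_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class Locus:
    id: str
    cls: str                     # coding | neutral | pseudogene
    biotype: str
    transcript: TranscriptModel
    orf: ORFRecord
    family: str | None = None
    translated: bool = False
    expression_specific: bool = False


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    loci: list[Locus]
    blocks: list[AlignmentBlock]
    track: ConservationTrack
    track_records: list[tuple]
    variants: list[VariantRecord]
    reads: pd.DataFrame
    fpkm: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, out / "genome.fa")
        write_gtf(self.transcripts, out / "annotation.gtf")
        sizes = {sp: len(self.genome["chr1"])
                 for b in self.blocks for sp in b.rows}
        write_maf(self.blocks, out / "alignment.maf", src_sizes=sizes)
        with open(out / "track.bedGraph", "w") as fh:
            for chrom, start, end, score in self.track_records:
                fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")
        write_variants(self.variants, out / "snps.vcf",
                       contigs={"chr1": len(self.genome["chr1"])})
        bed = self.reads.copy()
        bed["end"] = bed["position"] + 1
        bed[["chrom", "position", "end", "transcript", "length",
             "strand"]].to_csv(out / "reads.bed", sep="\t", header=False,
                               index=False)
        self.fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(self.config.tree_newick + "\n")


# ---------------------------------------------------------------------------
# sequence-level simulators
# ---------------------------------------------------------------------------

def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop, non-ATG internal codons + a stop codon."""
    internal = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(internal) + str(stop)


def random_dna(rng: np.random.Generator, n: int, avoid_atg: bool = False
               ) -> str:
    seq = "".join(rng.choice(list("ACGT"), size=n))
    if avoid_atg:
        seq = seq.replace("ATG", "ACG")
    return seq


@lru_cache(maxsize=None)
def _synonymous_variants(codon: str) -> list[str]:
    aa = str(Seq(codon).translate())
    out = []
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            mut = codon[:i] + nt + codon[i + 1:]
            if mut not in STOP_CODONS and str(Seq(mut).translate()) == aa:
                out.append(mut)
    return out


@lru_cache(maxsize=None)
def _nonsynonymous_variants(codon: str) -> list[str]:
    aa = str(Seq(codon).translate())
    out = []
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            mut = codon[:i] + nt + codon[i + 1:]
            if mut not in STOP_CODONS and str(Seq(mut).translate()) != aa:
                out.append(mut)
    return out


@dataclass
class _SpeciesState:
    """Per-species sequence aligned to reference positions."""

    bases: list[str]                       # '' = deleted
    insertions: dict[int, str] = field(default_factory=dict)


def _mutate(state: _SpeciesState, t: float, mode: str, region: tuple[int, int],
            cfg: SimulationConfig, rng: np.random.Generator,
            force_event: str | None = None) -> _SpeciesState:
    """Apply one branch of evolution.  ``region`` is the ORF span within the
    locus (codon-aware evolution inside, neutral outside for coding mode).
    """
    bases = list(state.bases)
    ins = dict(state.insertions)
    lo, hi = region
    if mode == "coding":
        for ci in range(lo // 3 + 1, hi // 3 - 1):
            start = ci * 3
            codon = "".join(bases[start:start + 3])
            if len(codon) != 3:
                continue
            if rng.random() < cfg.syn_rate * t:
                variants = _synonymous_variants(codon)
                if variants:
                    codon = variants[rng.integers(len(variants))]
            if rng.random() < cfg.nonsyn_rate * t:
                variants = _nonsynonymous_variants(codon)
                if variants:
                    codon = variants[rng.integers(len(variants))]
            bases[start], bases[start + 1], bases[start + 2] = codon
        # flanks evolve neutrally
        for i in list(range(0, lo)) + list(range(hi, len(bases))):
            if bases[i] and rng.random() < cfg.neutral_rate * t:
                bases[i] = _other_base(bases[i], rng)
    else:
        for i in range(len(bases)):
            if bases[i] and rng.random() < cfg.neutral_rate * t:
                bases[i] = _other_base(bases[i], rng)
    if force_event == "frameshift":
        span = rng.integers(1, 3)          # 1 or 2 nt
        pos = int(rng.integers(lo + 3, hi - 3 - span))
        if rng.random() < 0.5:
            for p in range(pos, pos + span):
                bases[p] = ""
        else:
            ins[pos] = random_dna(rng, int(span))
    elif force_event == "inframe_del":
        pos = int(rng.integers(lo // 3 + 1, hi // 3 - 1)) * 3
        for p in range(pos, pos + 3):
            bases[p] = ""
    elif force_event == "nonsense":
        ci = int(rng.integers(lo // 3 + 1, hi // 3 - 1))
        stop = sorted(STOP_CODONS)[rng.integers(3)]
        bases[ci * 3], bases[ci * 3 + 1], bases[ci * 3 + 2] = stop
    return _SpeciesState(bases=bases, insertions=ins)


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


def evolve_alignment(ref_seq: str, tree, cfg: SimulationConfig,
                     mode: str, orf_span: tuple[int, int],
                     chrom: str, start: int,
                     rng: np.random.Generator) -> AlignmentBlock:
    """Evolve ``ref_seq`` down the species tree and emit one MAF-style
    block.  The reference leaf row always equals the reference sequence
    (branches on the root-to-reference path do not mutate)."""
    ref_leaf = next(l for l in tree.get_terminals()
                    if l.name == cfg.ref_species)
    ref_path = {id(c) for c in [tree.root] + tree.get_path(ref_leaf)}
    root_state = _SpeciesState(bases=list(ref_seq))
    leaf_states: dict[str, _SpeciesState] = {}

    def recurse(clade, state: _SpeciesState):
        for child in clade.clades:
            t = child.branch_length or 0.0
            if id(child) in ref_path:
                child_state = _SpeciesState(bases=list(state.bases),
                                            insertions=dict(state.insertions))
            else:
                child_state = _mutate(state, t, mode, orf_span, cfg, rng)
            if child.is_terminal():
                leaf_states[child.name] = child_state
            else:
                recurse(child, child_state)

    recurse(tree.root, root_state)
    leaf_states[cfg.ref_species] = root_state
    # per-species stochastic events
    species = sorted(leaf_states)
    for sp in species:
        if sp == cfg.ref_species:
            continue
        if mode == "neutral" and rng.random() < cfg.indel_prob:
            leaf_states[sp] = _mutate(leaf_states[sp], 0.0, mode, orf_span,
                                      cfg, rng, force_event="frameshift")
        elif mode == "coding" and rng.random() < cfg.inframe_indel_prob:
            leaf_states[sp] = _mutate(leaf_states[sp], 0.0, mode, orf_span,
                                      cfg, rng, force_event="inframe_del")
        elif mode == "pseudogene":
            event = "frameshift" if rng.random() < 0.5 else "nonsense"
            leaf_states[sp] = _mutate(leaf_states[sp], 0.0, "neutral",
                                      orf_span, cfg, rng, force_event=event)
    return _states_to_block(ref_seq, leaf_states, cfg.ref_species,
                            chrom, start)


def _states_to_block(ref_seq: str, states: dict[str, _SpeciesState],
                     ref_species: str, chrom: str, start: int
                     ) -> AlignmentBlock:
    species = sorted(states)
    rows = {sp: [] for sp in species}
    for i in range(len(ref_seq)):
        # insertion columns, one set per inserting species
        for sp in species:
            inserted = states[sp].insertions.get(i, "")
            if inserted:
                for c in inserted:
                    for other in species:
                        rows[other].append(c if other == sp else "-")
        for sp in species:
            b = states[sp].bases[i] if sp != ref_species else ref_seq[i]
            rows[sp].append(b if b else "-")
    return AlignmentBlock(chrom, start, ref_species,
                          {sp: "".join(r) for sp, r in rows.items()}, {})


# ---------------------------------------------------------------------------
# SNPs, reads, expression
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _change_table(codon: str) -> tuple:
    """All 9 single-nucleotide changes of a codon as (pos, alt, is_syn)."""
    aa = str(Seq(codon).translate())
    out = []
    for j in range(3):
        for nt in "ACGT":
            if nt == codon[j]:
                continue
            mut = codon[:j] + nt + codon[j + 1:]
            syn = mut not in STOP_CODONS and str(Seq(mut).translate()) == aa
            out.append((j, nt, syn))
    return tuple(out)


_RC = str.maketrans("ACGT", "TGCA")


def simulate_snps(orf: ORFRecord, omega: float, density_per_kb: float,
                  rng: np.random.Generator,
                  rare_fraction: float = 0.1) -> list[VariantRecord]:
    """SNPs over one ORF with true dN/dS = ``omega``: every possible
    single-nucleotide change in an internal codon occurs independently,
    synonymous changes at a base rate and nonsynonymous ones at ``omega``
    times that rate, calibrated so the common (DAF >= 1 %) variants hit the
    requested overall density.  Rare (DAF < 1 %) variants are added on top,
    at ``rare_fraction`` of the common rate, as filter fodder."""
    L = len(orf.nt_seq)
    s_total = n_total = 0.0
    for ci in range(1, orf.n_codons - 1):
        s, n = codon_sites(orf.nt_seq[3 * ci:3 * ci + 3])
        s_total += s
        n_total += n
    target = density_per_kb * L / 1000.0
    denom = s_total + omega * n_total
    rate = target / denom if denom > 0 else 0.0
    g_positions = [p for iv in orf.genomic_intervals
                   for p in range(iv.start, iv.end)]
    if orf.strand == "-":
        g_positions.reverse()
    out = []
    for ci in range(1, orf.n_codons - 1):
        codon = orf.nt_seq[3 * ci:3 * ci + 3]
        for j, nt, syn in _change_table(codon):
            t_pos = 3 * ci + j
            p = rate / 3.0 * (1.0 if syn else omega)
            for rare in (False, True):
                if rng.random() >= (p * rare_fraction if rare else p):
                    continue
                daf = (float(rng.uniform(0.0005, 0.009)) if rare
                       else float(rng.uniform(0.02, 0.5)))
                ref_nt, alt_nt = codon[j], nt
                if orf.strand == "-":
                    ref_nt = ref_nt.translate(_RC)
                    alt_nt = alt_nt.translate(_RC)
                out.append(VariantRecord(
                    chrom=orf.chrom, pos=g_positions[t_pos],
                    ref=ref_nt, alt=alt_nt, daf=daf))
    return out


def simulate_orf_reads(rng: np.random.Generator, transcript_id: str,
                       chrom: str, t_offset: int,
                       orf_start: int, orf_end: int,
                       n_reads: int, frame_bias: float,
                       read_length: int, p_site_offset: int,
                       init_fraction: float = 0.1) -> list[dict]:
    """Ribosome-profiling 5' ends for one single-exon plus-strand ORF.

    P-sites land on a random codon; with probability ``frame_bias`` at
    codon position 1, else uniformly on positions 2/3; a fraction of reads
    comes from initiating ribosomes at the start codon (the peak that
    anchors metagene offset estimation).  The recorded raw 5' end is
    P-site - offset (consumers re-apply the offset)."""
    rows = []
    n_codons = (orf_end - orf_start) // 3
    for _ in range(n_reads):
        if frame_bias > 1 / 3 and rng.random() < init_fraction:
            codon, within = 0, 0
            p_site = orf_start + 3 * codon + within
            five_prime = p_site - p_site_offset
            rows.append({"chrom": chrom, "transcript": transcript_id,
                         "position": t_offset + five_prime,
                         "t_position": five_prime,
                         "length": read_length, "strand": "+"})
            continue
        codon = int(rng.integers(1, n_codons - 1))
        if rng.random() < frame_bias:
            within = 0
        else:
            within = int(rng.integers(1, 3))
        p_site = orf_start + 3 * codon + within
        five_prime = p_site - p_site_offset
        rows.append({"chrom": chrom, "transcript": transcript_id,
                     "position": t_offset + five_prime,
                     "t_position": five_prime,
                     "length": read_length, "strand": "+"})
    return rows


def simulate_expression(rng: np.random.Generator, n_samples: int,
                        specific: bool) -> np.ndarray:
    """FPKM across samples: broad expression is lognormal everywhere;
    specific expression is confined to one sample."""
    if specific:
        row = np.zeros(n_samples)
        row[rng.integers(n_samples)] = rng.lognormal(3.0, 0.5)
        return row
    return rng.lognormal(2.0, 0.5, size=n_samples)


def _families_separable(new_members: list[str],
                        accepted_members: list[str]) -> bool:
    """Reject candidate family members whose chance local-alignment
    similarity to any accepted member approaches the clustering cutoff.
    The E-value criterion is ignored (conservatively treated as passing)."""
    from .homology_clustering import (align_peptides, dynamic_cutoff,
                                      pid_eff, size_compatible)
    if not accepted_members:
        return True
    pool = {f"n{i}": s for i, s in enumerate(new_members)}
    pool.update({f"a{i}": s for i, s in enumerate(accepted_members)})
    for h in align_peptides(pool):
        if h.query_id.startswith("a") and h.subject_id.startswith("a"):
            continue
        if h.query_id.startswith("n") and h.subject_id.startswith("n"):
            continue
        if not size_compatible(h.query_length, h.subject_length):
            continue
        margin = 0.95 * dynamic_cutoff(h.query_length, h.subject_length)
        if pid_eff(h) > margin:
            return False
    return True


def simulate_peptide_families(rng: np.random.Generator, n_families: int = 20,
                              species: tuple[str, ...] = ("hs", "mm", "dr"),
                              length_range: tuple[int, int] = (25, 40),
                              within_divergence: float = 0.05
                              ) -> tuple[dict[str, str], dict[str, str],
                                         dict[str, str]]:
    """Planted cross-species homolog families: near-identical peptides
    within a family (pairwise identity >= 90 %), dissimilar between
    families (family seeds are rejection-sampled until no chance alignment
    approaches the clustering cutoff).  Returns (peptides, species_of,
    family_of)."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    peptides, species_of, family_of = {}, {}, {}
    accepted: list[str] = []
    for fam in range(n_families):
        for _ in range(100):
            length = int(rng.integers(length_range[0],
                                      length_range[1] + 1))
            base = "".join(rng.choice(alphabet, size=length))
            members = []
            for _sp in species:
                seq = list(base)
                for i in range(length):
                    if rng.random() < within_divergence:
                        seq[i] = alphabet[rng.integers(20)]
                members.append("".join(seq))
            if _families_separable(members, accepted):
                break
        else:
            raise RuntimeError("could not plant a separable family")
        accepted.extend(members)
        for sp, seq in zip(species, members):
            name = f"fam{fam:03d}_{sp}"
            peptides[name] = seq
            species_of[name] = sp
            family_of[name] = f"fam{fam:03d}"
    return peptides, species_of, family_of


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_locus_set(config: SimulationConfig) -> SimulatedBundle:
    """Generate one complete, internally consistent fixture bundle."""
    from Bio import Phylo
    from io import StringIO

    rng = np.random.default_rng(config.seed)
    tree = Phylo.read(StringIO(config.tree_newick), "newick")
    chrom = "chr1"
    classes = ([("coding", "protein_coding")] * config.n_annotated
               + [("coding", "lincRNA")] * config.n_novel
               + [("neutral", "snoRNA")] * config.n_neutral_ncrna
               + [("neutral", "lincRNA")] * config.n_neutral_linc
               + [("pseudogene", "processed_pseudogene")]
               * config.n_pseudogene)
    genome_parts = [random_dna(rng, config.spacer_len)]
    cursor = config.spacer_len
    loci: list[Locus] = []
    blocks: list[AlignmentBlock] = []
    track_records: list[tuple] = []
    variants: list[VariantRecord] = []
    read_rows: list[dict] = []
    fpkm_rows = {}
    for idx, (cls, biotype) in enumerate(classes):
        n_codons = int(rng.integers(*config.orf_codons))
        orf_seq = random_orf(rng, n_codons)
        utr5 = random_dna(rng, config.utr_len, avoid_atg=True)
        utr3 = random_dna(rng, config.utr_len, avoid_atg=True)
        t_seq = utr5 + orf_seq + utr3
        t_start = cursor
        t_end = cursor + len(t_seq)
        lid = f"locus{idx:04d}"
        tid = f"T{idx:04d}"
        exon = GenomeInterval(chrom, t_start, t_end, "+")
        orf_g = GenomeInterval(chrom, t_start + config.utr_len,
                               t_start + config.utr_len + len(orf_seq), "+")
        cds = [orf_g] if biotype == "protein_coding" else None
        transcript = TranscriptModel(
            id=tid, gene_id=f"G{idx:04d}", biotype=biotype, exons=[exon],
            cds=cds, gene_biotype=biotype)
        orf = ORFRecord(
            id=f"{chrom}:{orf_g.start}-{orf_g.end}:+:{n_codons}",
            transcript_ids=[tid], genomic_intervals=[orf_g],
            transcript_start=config.utr_len,
            transcript_end=config.utr_len + len(orf_seq),
            nt_seq=orf_seq,
            aa_seq=str(Seq(orf_seq[:-3]).translate()))
        orf_span = (config.utr_len, config.utr_len + len(orf_seq))
        blocks.append(evolve_alignment(t_seq, tree, config, cls, orf_span,
                                       chrom, t_start, rng))
        # conservation track
        if cls == "coding":
            track_records.append((chrom, t_start, orf_g.start, 0.2))
            track_records.append((chrom, orf_g.start, orf_g.end, 0.85))
            track_records.append((chrom, orf_g.end, t_end, 0.2))
        else:
            track_records.append((chrom, t_start, t_end, 0.3))
        # SNPs
        omega = (config.omega_coding if cls == "coding"
                 else config.omega_neutral)
        variants.extend(simulate_snps(orf, omega, config.snp_density_per_kb,
                                      rng))
        # ribosome reads
        translated = cls == "coding"
        bias = config.frame_bias if translated else 1 / 3
        read_rows.extend(simulate_orf_reads(
            rng, tid, chrom, t_start, *orf_span,
            n_reads=config.reads_per_orf, frame_bias=bias,
            read_length=config.read_length,
            p_site_offset=config.p_site_offset))
        # expression
        specific = cls != "coding"
        fpkm_rows[tid] = simulate_expression(rng, config.n_samples, specific)
        loci.append(Locus(id=lid, cls=cls, biotype=biotype,
                          transcript=transcript, orf=orf,
                          translated=translated,
                          expression_specific=specific))
        genome_parts.append(t_seq)
        genome_parts.append(random_dna(rng, config.spacer_len))
        cursor = t_end + config.spacer_len
    genome = {chrom: "".join(genome_parts)}
    track = ConservationTrack.from_intervals(track_records)
    reads = pd.DataFrame(read_rows)
    fpkm = pd.DataFrame(
        fpkm_rows,
        index=[f"sample{i}" for i in range(config.n_samples)]).T
    truth = pd.DataFrame([{
        "locus": l.id, "transcript": l.transcript.id, "orf_id": l.orf.id,
        "class": l.cls, "biotype": l.biotype,
        "omega": (config.omega_coding if l.cls == "coding"
                  else config.omega_neutral),
        "frame_bias": config.frame_bias if l.translated else 1 / 3,
        "translated": l.translated,
        "expression_specific": l.expression_specific,
    } for l in loci])
    return SimulatedBundle(
        config=config, genome=genome,
        transcripts=[l.transcript for l in loci], loci=loci, blocks=blocks,
        track=track, track_records=track_records, variants=variants,
        reads=reads, fpkm=fpkm, truth=truth)
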