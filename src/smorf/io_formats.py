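"""Readers and writers for the standard formats the pipeline touches.

Everything is normalized to a single internal coordinate convention:
0-based, half-open, genomic forward strand.  GTF (1-based inclusive) and
MAF are converted on read.  Sequence-level operations on minus-strand
transcripts work in transcript orientation; genomic outputs are converted
back on write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, Phylo, SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Genomic interval, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains(self, other: "GenomeInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass
class TranscriptModel:
    """A spliced transcript with optional CDS annotation.

    Exons are stored sorted by genomic coordinate; transcript orientation
    (5'->3') is derived from the strand.  ``stranded=False`` marks entries
    (for example some lincRNA catalogs) that must be scanned on both strands.
    """

    id: str
    gene_id: str
    biotype: str
    exons: list[GenomeInterval]
    cds: list[GenomeInterval] | None = None
    gene_biotype: str | None = None
    source_catalog: str = "reference"
    stranded: bool = True

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.id}: overlapping exons")
        if self.cds:
            self.cds = sorted(self.cds, key=lambda e: e.start)
            for c in self.cds:
                if not any(e.contains(c) for e in self.exons):
                    raise ValidationError(f"{self.id}: CDS outside exons")
        if self.gene_biotype is None:
            self.gene_biotype = self.biotype

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    # ---- coordinate mapping (bijective on exonic positions) ----

    def genomic_positions(self) -> list[int]:
        """Genomic position of every transcript position, 5'->3'."""
        pos = [p for e in self.exons for p in range(e.start, e.end)]
        if self.strand == "-":
            pos.reverse()
        return pos

    def to_genomic(self, t_pos: int) -> int:
        if not 0 <= t_pos < self.length:
            raise IndexError(f"transcript position {t_pos} out of range")
        remaining = t_pos
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        for e in exons:
            if remaining < len(e):
                if self.strand == "-":
                    return e.end - 1 - remaining
                return e.start + remaining
            remaining -= len(e)
        raise AssertionError("unreachable")

    def to_transcript(self, g_pos: int) -> int:
        offset = 0
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        for e in exons:
            if e.start <= g_pos < e.end:
                if self.strand == "-":
                    return offset + (e.end - 1 - g_pos)
                return offset + (g_pos - e.start)
            offset += len(e)
        raise IndexError(f"genomic position {g_pos} not exonic in {self.id}")

    def interval_chain(self, t_start: int, t_end: int) -> list[GenomeInterval]:
        """Genomic intervals (sorted by coordinate) covering the spliced
        transcript range [t_start, t_end)."""
        if not (0 <= t_start < t_end <= self.length):
            raise IndexError(f"range {t_start}-{t_end} out of transcript")
        positions = sorted(self.genomic_positions()[t_start:t_end])
        out: list[GenomeInterval] = []
        run_start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomeInterval(self.chrom, run_start, prev + 1,
                                          self.strand))
                run_start = p
            prev = p
        out.append(GenomeInterval(self.chrom, run_start, prev + 1, self.strand))
        return out

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][e.start:e.end] for e in self.exons)
        seq = seq.upper()
        return revcomp(seq) if self.strand == "-" else seq

    def cds_transcript_range(self) -> tuple[int, int] | None:
        """CDS span in transcript coordinates (half-open), or None."""
        if not self.cds:
            return None
        pos = sorted(self.to_transcript(p)
                     for c in self.cds for p in (c.start, c.end - 1))
        return pos[0], pos[-1] + 1


@dataclass
class AlignmentBlock:
    """One MAF block normalized to reference forward-strand coordinates.

    ``rows`` maps species name to its gapped sequence; the reference row may
    itself contain gaps where other species carry insertions.  The insertion
    index records, per species, the total length of reference-absent sequence
    anchored at each reference coordinate (the coordinate of the next
    reference base).
    """

    chrom: str
    start: int
    ref_species: str
    rows: dict[str, str]
    insertions: dict[str, dict[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError("alignment rows of unequal length")
        if not self.insertions:
            self.insertions = self._build_insertion_index()

    @property
    def ref_row(self) -> str:
        return self.rows[self.ref_species]

    @property
    def end(self) -> int:
        return self.start + sum(1 for c in self.ref_row if c != "-")

    def _ref_coords(self) -> list[int]:
        """Per column: reference coordinate of the column's base, or of the
        next reference base for insertion columns."""
        coords, pos = [], self.start
        for c in self.ref_row:
            coords.append(pos)
            if c != "-":
                pos += 1
        return coords

    def _build_insertion_index(self) -> dict[str, dict[int, int]]:
        coords = self._ref_coords()
        index: dict[str, dict[int, int]] = {}
        for sp, row in self.rows.items():
            if sp == self.ref_species:
                continue
            ins: dict[int, int] = {}
            for col, (rc, sc) in enumerate(zip(self.ref_row, row)):
                if rc == "-" and sc != "-":
                    ins[coords[col]] = ins.get(coords[col], 0) + 1
            if ins:
                index[sp] = ins
        return index

    def species_profile(self, species: str) -> str:
        """Species bases over reference coordinates [start, end);
        '-' where the species has a gap at a reference base."""
        if species not in self.rows:
            return "-" * (self.end - self.start)
        out = []
        for rc, sc in zip(self.ref_row, self.rows[species]):
            if rc != "-":
                out.append(sc)
        return "".join(out)

    def clip(self, start: int, end: int) -> "AlignmentBlock | None":
        """Restrict to reference coordinates [start, end)."""
        start = max(start, self.start)
        end = min(end, self.end)
        if start >= end:
            return None
        coords = self._ref_coords()
        cols = [i for i, (c, rc) in enumerate(zip(coords, self.ref_row))
                if start <= c < end and not (rc == "-" and c == start)]
        # keep insertion columns only when anchored strictly inside the clip
        rows = {sp: "".join(row[i] for i in cols)
                for sp, row in self.rows.items()}
        return AlignmentBlock(self.chrom, start, self.ref_species, rows, {})


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1].

    Positions absent from the input read as ``default`` (0.0)."""

    def __init__(self, default: float = 0.0):
        self.default = default
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_intervals(cls, records, default: float = 0.0):
        """records: iterable of (chrom, start, end, score)."""
        track = cls(default)
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end),
                                                   float(score)))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([i[0] for i in ivs])
            ends = np.array([i[1] for i in ivs])
            vals = np.array([i[2] for i in ivs])
            track._chroms[chrom] = (starts, ends, vals)
        return track

    def score(self, chrom: str, pos: int) -> float:
        if chrom not in self._chroms:
            return self.default
        starts, ends, vals = self._chroms[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(vals[i])
        return self.default

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        return np.array([self.score(chrom, p) for p in range(start, end)])


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with the annotations the selection
    analysis filters on."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    daf: float | None = None
    minus_strand: bool = False
    in_repeat: bool = False

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(f"not a SNV: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValidationError("ref == alt")
        if self.daf is not None and not 0 <= self.daf <= 1:
            raise ValidationError(f"DAF {self.daf} outside [0,1]")


# ---------------------------------------------------------------------------
# annotation (GTF / BED12)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"malformed GTF attribute column at line {lineno}:"
                             f" {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path, source_catalog: str = "reference") -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon and CDS features)."""
    exons: dict[str, list[GenomeInterval]] = {}
    cds: dict[str, list[GenomeInterval]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"GTF line {lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = \
                fields[:9]
            if ftype not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(attr, lineno)
            try:
                tid = attrs["transcript_id"]
            except KeyError:
                raise ParseError(f"GTF line {lineno}: missing transcript_id")
            iv = GenomeInterval(chrom, int(start) - 1, int(end),
                                strand if strand in "+-" else ".")
            if ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
            meta.setdefault(tid, {}).update(
                gene_id=attrs.get("gene_id", tid),
                biotype=attrs.get("transcript_biotype",
                                  attrs.get("biotype", "protein_coding")),
                gene_biotype=attrs.get("gene_biotype"),
                stranded=strand in "+-")
    out = []
    for tid, ex in exons.items():
        m = meta[tid]
        out.append(TranscriptModel(
            id=tid, gene_id=m["gene_id"], biotype=m["biotype"],
            exons=ex, cds=cds.get(tid), gene_biotype=m["gene_biotype"],
            source_catalog=source_catalog, stranded=m["stranded"]))
    if not out:
        log.warning("no transcripts parsed from %s", path)
    return out


def read_bed12(path, source_catalog: str,
               biotype: str = "lincRNA") -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"BED12 line {lineno}: expected 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            stranded = strand in "+-"
            exons = [GenomeInterval(chrom, start + o, start + o + s,
                                    strand if stranded else ".")
                     for o, s in zip(offsets, sizes)]
            out.append(TranscriptModel(
                id=name, gene_id=name, biotype=biotype, exons=exons,
                source_catalog=source_catalog, stranded=stranded))
    return out


def read_annotation(path, extra_catalogs=None,
                    extra_biotype: str = "lincRNA") -> list[TranscriptModel]:
    """Read the reference GTF and merge optional extra catalogs
    (GTF or BED12).

    Non-reference entries receive ``extra_biotype`` unless the catalog file
    itself carries biotypes.  Transcripts duplicating an existing exon chain
    exactly are dropped.
    """
    transcripts = read_gtf(path)
    seen = {tuple(t.exons) for t in transcripts}
    for cat in (extra_catalogs or []):
        cat = str(cat)
        if cat.endswith((".bed", ".bed12")):
            extra = read_bed12(cat, source_catalog=cat, biotype=extra_biotype)
        else:
            extra = read_gtf(cat, source_catalog=cat)
            for t in extra:
                t.biotype = extra_biotype
                t.gene_biotype = extra_biotype
        for t in extra:
            key = tuple(t.exons)
            if key not in seen:
                seen.add(key)
                transcripts.append(t)
    return transcripts


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                     f'transcript_biotype "{t.biotype}"; '
                     f'gene_biotype "{t.gene_biotype}";')
            strand = t.strand if t.stranded else "."
            for e in t.exons:
                fh.write("\t".join([t.chrom, t.source_catalog, "exon",
                                    str(e.start + 1), str(e.end), ".",
                                    strand, ".", attrs]) + "\n")
            for c in (t.cds or []):
                fh.write("\t".join([t.chrom, t.source_catalog, "CDS",
                                    str(c.start + 1), str(c.end), ".",
                                    strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# alignments (MAF)
# ---------------------------------------------------------------------------

def read_alignment(path, region: GenomeInterval | None = None,
                   ref_species: str | None = None) -> list[AlignmentBlock]:
    """Read MAF blocks intersecting ``region`` (all blocks if None), clipped
    to it.  Species names are the part of the MAF src before the first dot.
    The reference species is the first row of each block unless given."""
    blocks = []
    with open(path) as fh:
        for msa in AlignIO.parse(fh, "maf"):
            first = msa[0]
            ref = ref_species or first.id.split(".")[0]
            chrom = first.id.split(".", 1)[1] if "." in first.id else first.id
            start = int(first.annotations["start"])
            rows = {}
            for rec in msa:
                rows[rec.id.split(".")[0]] = str(rec.seq).upper()
            block = AlignmentBlock(chrom, start, ref, rows, {})
            if region is None:
                blocks.append(block)
                continue
            if block.chrom != region.chrom:
                continue
            clipped = block.clip(region.start, region.end)
            if clipped is not None:
                blocks.append(clipped)
    if region is not None and not blocks:
        log.warning("no alignment blocks intersect %s:%d-%d",
                    region.chrom, region.start, region.end)
    return sorted(blocks, key=lambda b: (b.chrom, b.start))


def write_maf(blocks: list[AlignmentBlock], path,
              src_sizes: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            order = [b.ref_species] + [s for s in b.rows if s != b.ref_species]
            for sp in order:
                row = b.rows[sp]
                size = sum(1 for c in row if c != "-")
                start = b.start if sp == b.ref_species else 0
                total = (src_sizes or {}).get(sp, max(b.end, size))
                fh.write(f"s {sp}.{b.chrom} {start} {size} + {total} {row}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# tracks, variants, trees
# ---------------------------------------------------------------------------

def read_track(path, default: float = 0.0) -> ConservationTrack:
    """Read a bedGraph (or variableStep wig) conservation track."""
    records = []
    chrom = None
    span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom, span = fields["chrom"], int(fields.get("span", 1))
                continue
            f = line.split()
            if chrom is not None and len(f) == 2:   # wig data line, 1-based
                pos = int(f[0]) - 1
                records.append((chrom, pos, pos + span, float(f[1])))
            elif len(f) >= 4:
                records.append((f[0], int(f[1]), int(f[2]), float(f[3])))
            else:
                raise ParseError(f"track line {lineno}: cannot parse {line!r}")
    return ConservationTrack.from_intervals(records, default=default)


def read_variants(path) -> list[VariantRecord]:
    """Read SNVs from a minimal VCF (INFO keys DAF, REPEAT, STRAND).

    No filters are applied here; multi-allelic records are split."""
    import pysam
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                daf = rec.info.get("DAF")
                if isinstance(daf, tuple):
                    daf = daf[0]
                out.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alt=alt,
                    daf=float(daf) if daf is not None else None,
                    minus_strand=str(rec.info.get("STRAND", "+")) == "-",
                    in_repeat=bool(rec.info.get("REPEAT", False))))
    return out


def write_variants(variants: list[VariantRecord], path,
                   contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DAF,Number=1,Type=Float,'
                 'Description="Derived allele frequency">\n')
        fh.write('##INFO=<ID=REPEAT,Number=0,Type=Flag,'
                 'Description="Falls in a repeat-masked region">\n')
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,'
                 'Description="Annotation strand">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = [f"STRAND={'-' if v.minus_strand else '+'}"]
            if v.daf is not None:
                info.append(f"DAF={v.daf:g}")
            if v.in_repeat:
                info.append("REPEAT")
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                     f"{';'.join(info)}\n")


def read_tree(path):
    """Read a rooted species tree from Newick; leaf names must be unique."""
    tree = Phylo.read(str(path), "newick")
    names = [leaf.name for leaf in tree.get_terminals()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf names in species tree")
    return tree


# ---------------------------------------------------------------------------
# sequences and tables
# ---------------------------------------------------------------------------

def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path),
                                                                "fasta")}


def write_genome(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed_reads(path) -> pd.DataFrame:
    """Read ribosome-profiling 5' ends from BED6: chrom, 5'-end position
    (start), read length in the score column, strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "length",
                            "strand"])
    return df
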