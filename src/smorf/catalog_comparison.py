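"""Map external sORF catalogs onto the analyzed ORF set.

Catalog entries may be genomic coordinates (matched on the ORF stop-codon
coordinate), protein sequences (exact amino-acid match), or tryptic
peptides (substring match requiring a preceding lysine/arginine or the
protein N-terminus, with or without the initiator methionine).  Each entry
receives one status: predicted_here, analyzed_only, or unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenomeInterval
from .orf_catalog import ORFRecord

ENTRY_TYPES = ("coords", "protein", "peptide")


@dataclass(frozen=True)
class CatalogEntry:
    id: str
    entry_type: str          # coords | protein | peptide
    value: object            # GenomeInterval (stop codon) or str

    def __post_init__(self):
        if self.entry_type not in ENTRY_TYPES:
            raise ValueError(f"unknown entry type {self.entry_type!r}")


def _tryptic_match(peptide: str, protein: str) -> bool:
    """Substring match with a preceding K/R; N-terminal peptides (with or
    without the cleaved initiator Met) also count."""
    start = protein.find(peptide)
    while start != -1:
        if start == 0 or protein[start - 1] in "KR":
            return True
        if start == 1 and protein[0] == "M":
            return True
        start = protein.find(peptide, start + 1)
    return False


def match_catalog(entries: list[CatalogEntry],
                  analyzed: list[ORFRecord],
                  predicted_ids: set[str]) -> dict[str, str]:
    """Status per entry id against the analyzed ORF set and the prediction
    subset.  Entry files must be single-typed; duplicates collapse to one
    status."""
    types = {e.entry_type for e in entries}
    if len(types) > 1:
        raise ValueError(f"mixed-type catalog: {sorted(types)}")
    by_stop = {}
    by_protein: dict[str, list[ORFRecord]] = {}
    for orf in analyzed:
        s = orf.stop_codon_interval
        by_stop.setdefault((s.chrom, s.start, s.end), []).append(orf)
        by_protein.setdefault(orf.aa_seq, []).append(orf)
    result: dict[str, str] = {}
    for e in entries:
        hits: list[ORFRecord] = []
        if e.entry_type == "coords":
            iv: GenomeInterval = e.value
            hits = by_stop.get((iv.chrom, iv.start, iv.end), [])
        elif e.entry_type == "protein":
            hits = by_protein.get(str(e.value), [])
        else:
            pep = str(e.value)
            hits = [o for o in analyzed if _tryptic_match(pep, o.aa_seq)]
        if not hits:
            result[e.id] = "unmatched"
        elif any(o.id in predicted_ids for o in hits):
            result[e.id] = "predicted_here"
        else:
            result[e.id] = "analyzed_only"
    return result
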