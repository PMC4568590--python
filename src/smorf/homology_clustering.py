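"""Cross-species homology clustering of sORF-encoded peptides.

Short peptides need a length-aware identity criterion: hits are kept when
the effective percent identity PID_eff = PID * alignment_length /
query_length exceeds a dynamic cutoff 30 + 70*exp(-(qlen+slen)/20), sizes
deviate by at most 20 %, and E < 10.  Mutual edges form within-species
paralog clusters; reciprocal best hits connect clusters across species;
singletons are dropped and isomorphic clusters are collapsed with a
multiplicity count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a blast-style tabular peptide hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    query_length: int
    subject_length: int


@dataclass
class Cluster:
    members: list[str]
    species: set[str]
    categories: dict[str, str]
    contains_novel: bool
    multiplicity: int = 1


def pid_eff(hit: AlignmentHit) -> float:
    """Effective percent identity of one directed hit."""
    if hit.query_length == 0:
        raise ValueError("query length 0")
    return hit.percent_identity * hit.alignment_length / hit.query_length


def dynamic_cutoff(qlen: int, slen: int) -> float:
    """Length-dependent PID_eff cutoff: short pairs need near-identity."""
    return 30.0 + 70.0 * math.exp(-(qlen + slen) / 20.0)


def size_compatible(qlen: int, slen: int, max_deviation: float = 0.20) -> bool:
    return abs(qlen - slen) / max(qlen, slen) <= max_deviation


def build_cluster_graph(hits: list[AlignmentHit],
                        species_of: dict[str, str],
                        category_of: dict[str, str] | None = None,
                        novel_categories: set[str] = frozenset(
                            {"lincRNA", "utr3", "utr5", "cds_overlap",
                             "other"}),
                        e_max: float = 10.0) -> list[Cluster]:
    """Construct the homology graph and return its clusters (no singletons).

    Construction order: directed edge iff size-compatible, E < e_max, and
    PID_eff above the dynamic cutoff (each directed hit tested with its own
    query length); keep mutual edges only; within-species connected
    components form paralog clusters; between species only reciprocal-best
    cluster pairs (best = max PID_eff over member pairs, ties by lower
    E-value then lexicographic id) are connected; singleton clusters are
    dropped.
    """
    category_of = category_of or {}
    directed: dict[tuple[str, str], AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: (h.e_value, h.query_id, h.subject_id)):
        if h.query_id == h.subject_id:
            continue
        if not size_compatible(h.query_length, h.subject_length):
            continue
        if h.e_value >= e_max:
            continue
        if pid_eff(h) <= dynamic_cutoff(h.query_length, h.subject_length):
            continue
        directed.setdefault((h.query_id, h.subject_id), h)
    mutual = nx.Graph()
    for node in species_of:
        mutual.add_node(node)
    for (q, s), h in directed.items():
        if (s, q) in directed and not mutual.has_edge(q, s):
            back = directed[(s, q)]
            mutual.add_edge(q, s,
                            pid_eff=max(pid_eff(h), pid_eff(back)),
                            e_value=min(h.e_value, back.e_value))
    # within-species paralog clusters
    paralog_id: dict[str, int] = {}
    n_clusters = 0
    for sp in sorted(set(species_of.values())):
        nodes = [n for n in mutual if species_of[n] == sp]
        sub = mutual.subgraph(nodes)
        for comp in nx.connected_components(sub):
            for n in comp:
                paralog_id[n] = n_clusters
            n_clusters += 1
    # best inter-species link per ordered cluster pair
    best: dict[tuple[int, int], tuple] = {}
    for q, s, data in mutual.edges(data=True):
        if species_of[q] == species_of[s]:
            continue
        for a, b in ((q, s), (s, q)):
            key = (paralog_id[a], paralog_id[b])
            cand = (-data["pid_eff"], data["e_value"], min(a, b), max(a, b))
            if key not in best or cand < best[key]:
                best[key] = cand
    # reciprocal best hits between paralog clusters, per species pair
    cluster_species = {cid: species_of[n]
                       for n, cid in paralog_id.items()}
    partners: dict[tuple[int, str], tuple] = {}
    for (ca, cb), cand in best.items():
        key = (ca, cluster_species[cb])
        if key not in partners or (cand, cb) < partners[key]:
            partners[key] = (cand, cb)
    final = nx.Graph()
    final.add_nodes_from(mutual.nodes)
    for q, s, _ in mutual.edges(data=True):
        if species_of[q] == species_of[s]:
            final.add_edge(q, s)
    for (ca, sp_b), (_, cb) in partners.items():
        back = partners.get((cb, cluster_species[ca]))
        if back is not None and back[1] == ca:
            # connect the clusters through their best member pair
            cand = best[(ca, cb)]
            final.add_edge(cand[2], cand[3])
    clusters = []
    for comp in nx.connected_components(final):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        cats = {m: category_of.get(m, "unknown") for m in members}
        clusters.append(Cluster(
            members=members,
            species={species_of[m] for m in members},
            categories=cats,
            contains_novel=any(c in novel_categories
                               for c in cats.values())))
    clusters.sort(key=lambda c: c.members)
    return clusters


def _signature(cluster: Cluster, species_of: dict[str, str]) -> tuple:
    """Canonical signature treating sORFs of the same species and category
    as equivalent."""
    labels = sorted((species_of[m], cluster.categories[m])
                    for m in cluster.members)
    return tuple(labels)


def collapse_isomorphic(clusters: list[Cluster],
                        species_of: dict[str, str],
                        require_multi_species: bool = True,
                        require_novel: bool = True
                        ) -> list[Cluster]:
    """Merge clusters with identical (species, category) signatures,
    recording multiplicity; optionally keep only clusters spanning >= 2
    species with >= 1 novel member (the reporting rule)."""
    by_sig: dict[tuple, Cluster] = {}
    for c in clusters:
        sig = _signature(c, species_of)
        if sig in by_sig:
            by_sig[sig].multiplicity += 1
        else:
            by_sig[sig] = Cluster(members=list(c.members),
                                  species=set(c.species),
                                  categories=dict(c.categories),
                                  contains_novel=c.contains_novel,
                                  multiplicity=1)
    out = []
    for c in by_sig.values():
        if require_multi_species and len(c.species) < 2:
            continue
        if require_novel and not c.contains_novel:
            continue
        out.append(c)
    out.sort(key=lambda c: c.members)
    return out


# ---------------------------------------------------------------------------
# internal toy aligner (test fallback; real runs consume tabular hits)
# ---------------------------------------------------------------------------

def align_peptides(peptides: dict[str, str],
                   gap_open: float = 9.0, gap_extend: float = 1.0,
                   k: float = 0.13, lam: float = 0.32) -> list[AlignmentHit]:
    """All-vs-all local peptide alignment with a PAM30 matrix and a
    small-database Karlin-Altschul E-value approximation.  Intended for
    fixtures and tests; production runs consume external 12-column hits."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("PAM30")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    names = sorted(peptides)
    total_len = sum(len(s) for s in peptides.values())
    hits = []
    for q in names:
        for s in names:
            if q == s:
                continue
            alns = aligner.align(peptides[q], peptides[s])
            if len(alns) == 0 or alns.score <= 0:
                continue
            aln = alns[0]
            qa, sa = str(aln[0]), str(aln[1])
            length = len(qa)
            ident = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
            evalue = k * len(peptides[q]) * total_len * math.exp(
                -lam * aln.score)
            hits.append(AlignmentHit(
                query_id=q, subject_id=s,
                percent_identity=100.0 * ident / length if length else 0.0,
                alignment_length=length, e_value=evalue,
                query_length=len(peptides[q]),
                subject_length=len(peptides[s])))
    return hits


def read_hits(path) -> list[AlignmentHit]:
    """Read blast outfmt-6 style hits; query/subject lengths from columns
    13/14 when present, else from the alignment span."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qlen = int(f[12]) if len(f) > 12 else int(f[7])
            slen = int(f[13]) if len(f) > 13 else int(f[9])
            hits.append(AlignmentHit(
                query_id=f[0], subject_id=f[1],
                percent_identity=float(f[2]),
                alignment_length=int(f[3]), e_value=float(f[10]),
                query_length=qlen, subject_length=slen))
    return hits
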