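"""Selection signatures: length-adjusted score normalization,
conservation-matched control sampling, and SNP-based dN/dS with reciprocal
contingency tests.

Site counting is Nei-Gojobori style with equal mutation weights: each codon
contributes, per position, the fraction of the three possible
single-nucleotide changes that are synonymous; start and stop codons are
excluded from both site and SNP counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .orf_catalog import ORFRecord, STOP_CODONS
from .io_formats import VariantRecord

NUCLEOTIDES = "ACGT"


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class SnpCounts:
    n_syn: int = 0
    n_nonsyn: int = 0
    s_sites: float = 0.0
    n_sites: float = 0.0

    def __add__(self, other: "SnpCounts") -> "SnpCounts":
        return SnpCounts(self.n_syn + other.n_syn,
                         self.n_nonsyn + other.n_nonsyn,
                         self.s_sites + other.s_sites,
                         self.n_sites + other.n_sites)

    @property
    def dnds(self) -> float:
        """dN/dS = (nonsyn SNPs per nonsyn site) / (syn SNPs per syn site);
        +inf when no synonymous SNPs were observed."""
        if self.n_sites == 0 or self.s_sites == 0:
            return float("nan")
        dn = self.n_nonsyn / self.n_sites
        if self.n_syn == 0:
            return float("inf")
        ds = self.n_syn / self.s_sites
        return dn / ds


# ---------------------------------------------------------------------------
# length-adjusted scores
# ---------------------------------------------------------------------------

def adjusted_scores(scores, lengths, n_bins: int = 100,
                    min_bin_size: int = 20) -> np.ndarray:
    """Z-scores of ``scores`` within percentile bins of the length
    distribution; bins with fewer than ``min_bin_size`` members are merged
    with their nearest neighbor.  The population standard deviation is used;
    all-equal bins map to z = 0."""
    scores = np.asarray(scores, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    order = np.argsort(lengths, kind="stable")
    n = len(scores)
    edges = [int(round(n * k / n_bins)) for k in range(n_bins + 1)]
    bins = [order[a:b] for a, b in zip(edges, edges[1:]) if b > a]
    merged: list[np.ndarray] = []
    for b in bins:
        if merged and (len(b) < min_bin_size or len(merged[-1]) < min_bin_size):
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    if len(merged) > 1 and len(merged[-1]) < min_bin_size:
        merged[-2] = np.concatenate([merged[-2], merged[-1]])
        merged.pop()
    z = np.empty(n)
    for idx in merged:
        vals = scores[idx]
        sd = vals.std()
        z[idx] = 0.0 if sd == 0 else (vals - vals.mean()) / sd
    return z


# ---------------------------------------------------------------------------
# conservation-matched controls
# ---------------------------------------------------------------------------

class MatchingError(RuntimeError):
    pass


def select_matched_controls(candidate_cons, pool_ids, pool_scores, pool_cons,
                            seed: int = 0, max_attempts: int = 1000,
                            p_threshold: float = 0.1) -> list:
    """Sample control ORFs whose mean per-base conservation distribution is
    statistically indistinguishable from the candidates'.

    The pool is first restricted to the 20 % of entries with selection
    scores closest to zero, then stratified-sampled on deciles of the
    candidates' mean conservation until a two-sample rank test gives
    P > ``p_threshold`` (or ``max_attempts`` is exhausted)."""
    rng = np.random.default_rng(seed)
    candidate_cons = np.asarray(candidate_cons, dtype=float)
    pool_ids = np.asarray(pool_ids)
    pool_scores = np.asarray(pool_scores, dtype=float)
    pool_cons = np.asarray(pool_cons, dtype=float)
    cutoff = np.quantile(np.abs(pool_scores), 0.2)
    near_zero = np.abs(pool_scores) <= cutoff
    pool_ids, pool_cons = pool_ids[near_zero], pool_cons[near_zero]
    if pool_ids.size == 0:
        raise MatchingError("empty pool after score restriction")
    deciles = np.quantile(candidate_cons, np.linspace(0, 1, 11))
    deciles[0], deciles[-1] = -np.inf, np.inf
    cand_bins = np.digitize(candidate_cons, deciles[1:-1])
    pool_bins = np.digitize(pool_cons, deciles[1:-1])
    best_p = 0.0
    for _ in range(max_attempts):
        chosen = []
        for b in range(10):
            want = int((cand_bins == b).sum())
            if want == 0:
                continue
            avail = np.where(pool_bins == b)[0]
            if avail.size == 0:       # empty stratum: draw from whole pool
                avail = np.arange(pool_cons.size)
            chosen.extend(rng.choice(avail, size=want,
                                     replace=avail.size < want))
        if not chosen:
            break
        chosen = np.array(chosen)
        p = stats.mannwhitneyu(candidate_cons, pool_cons[chosen],
                               alternative="two-sided").pvalue
        best_p = max(best_p, float(p))
        if p > p_threshold:
            return list(pool_ids[chosen])
    raise MatchingError(
        f"conservation matching infeasible (best P = {best_p:.3g})")


# ---------------------------------------------------------------------------
# SNP dN/dS
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: per position,
    the fraction of the three single-nucleotide changes that preserve the
    amino acid.  Changes to stop codons count as nonsynonymous."""
    codon = codon.upper()
    aa = _translate(codon)
    s = 0.0
    for i in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            mut = codon[:i] + nt + codon[i + 1:]
            if mut not in STOP_CODONS and _translate(mut) == aa:
                syn += 1
        s += syn / 3
    return s, 3.0 - s


def snp_counts_for_orf(orf: ORFRecord,
                       variants: list[VariantRecord],
                       min_daf: float = 0.01,
                       exclude_boundary_codons: bool = True) -> SnpCounts:
    """Count synonymous/nonsynonymous SNPs and sites over one ORF.

    SNPs on the minus strand, in repeats, or with derived allele frequency
    below ``min_daf`` (when annotated) are removed first.  Start and stop
    codons are excluded from both site and SNP counting."""
    counts = SnpCounts()
    g_positions = [p for iv in orf.genomic_intervals
                   for p in range(iv.start, iv.end)]
    if orf.strand == "-":
        g_positions.reverse()
    pos_to_t = {g: i for i, g in enumerate(g_positions)}
    first = 1 if exclude_boundary_codons else 0
    last = orf.n_codons - (2 if exclude_boundary_codons else 1)
    for ci in range(first, last + 1):
        s, n = codon_sites(orf.nt_seq[3 * ci:3 * ci + 3])
        counts.s_sites += s
        counts.n_sites += n
    by_pos: dict[int, list[VariantRecord]] = {}
    for v in variants:
        if v.chrom != orf.chrom or v.pos not in pos_to_t:
            continue
        if v.minus_strand or v.in_repeat:
            continue
        if v.daf is not None and v.daf < min_daf:
            continue
        by_pos.setdefault(v.pos, []).append(v)
    for g_pos, vs in by_pos.items():
        t_pos = pos_to_t[g_pos]
        ci = t_pos // 3
        if ci < first or ci > last:
            continue
        codon = orf.nt_seq[3 * ci:3 * ci + 3]
        within = t_pos % 3
        for v in vs:
            ref, alt = v.ref, v.alt
            if orf.strand == "-":
                ref = ref.translate(_COMP)
                alt = alt.translate(_COMP)
            if codon[within] != ref.upper():
                continue  # annotation mismatch; skip rather than guess
            mut = codon[:within] + alt.upper() + codon[within + 1:]
            if mut in STOP_CODONS:
                counts.n_nonsyn += 1
            elif _translate(mut) == _translate(codon):
                counts.n_syn += 1
            else:
                counts.n_nonsyn += 1
    return counts


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def aggregate_counts(per_orf: list[SnpCounts]) -> SnpCounts:
    total = SnpCounts()
    for c in per_orf:
        total = total + c
    return total


def _one_sided_chi2(observed: SnpCounts, rates_from: SnpCounts) -> float:
    """One-sided X^2 P value that nonsynonymous SNPs in ``observed`` are
    depleted relative to the per-site SNP rates of ``rates_from``."""
    total_snps = observed.n_nonsyn + observed.n_syn
    if total_snps == 0 or rates_from.n_sites + rates_from.s_sites == 0:
        return 1.0
    rate_n = rates_from.n_nonsyn / rates_from.n_sites \
        if rates_from.n_sites else 0.0
    rate_s = rates_from.n_syn / rates_from.s_sites \
        if rates_from.s_sites else 0.0
    exp_n = rate_n * observed.n_sites
    exp_s = rate_s * observed.s_sites
    norm = total_snps / (exp_n + exp_s) if exp_n + exp_s > 0 else 0.0
    exp_n, exp_s = exp_n * norm, exp_s * norm
    if exp_n <= 0 or exp_s <= 0:
        return 1.0
    chi2 = ((observed.n_nonsyn - exp_n) ** 2 / exp_n
            + (observed.n_syn - exp_s) ** 2 / exp_s)
    p_two = stats.chi2.sf(chi2, df=1)
    if observed.n_nonsyn <= exp_n:  # depletion, the tested direction
        return float(p_two / 2)
    return float(1 - p_two / 2)


def reciprocal_chi2(candidate: SnpCounts, control: SnpCounts
                    ) -> tuple[float, float, float]:
    """Reciprocal one-sided X^2 tests for nonsynonymous depletion: candidate
    counts against control-derived expectations and vice versa (with the
    direction flipped).  Returns (p_candidate, p_control, max)."""
    p_cand = _one_sided_chi2(candidate, control)
    p_ctrl = 1.0 - _one_sided_chi2(control, candidate)
    return p_cand, p_ctrl, max(p_cand, p_ctrl)


def snp_dnds(orfs: list[ORFRecord], variants: list[VariantRecord],
             control_orfs: list[ORFRecord] | None = None,
             min_daf: float = 0.01) -> dict:
    """Aggregate dN/dS over a set of ORFs, with reciprocal X^2 P values
    against a control set when one is given."""
    counts = aggregate_counts(
        [snp_counts_for_orf(o, variants, min_daf=min_daf) for o in orfs])
    out = {"counts": counts, "dnds": counts.dnds}
    if control_orfs is not None:
        ctrl = aggregate_counts(
            [snp_counts_for_orf(o, variants, min_daf=min_daf)
             for o in control_orfs])
        p_cand, p_ctrl, p_max = reciprocal_chi2(counts, ctrl)
        out.update(control_counts=ctrl, control_dnds=ctrl.dnds,
                   p_candidate=p_cand, p_control=p_ctrl, p_value=p_max)
    return out
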