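# Methods

This note documents the models, conventions, and numerical choices behind
`smorf`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and ORF definition

All internal coordinates are 0-based, half-open, on the genomic forward
strand; GTF (1-based inclusive) and MAF inputs are converted on read.
Sequence-level operations on minus-strand transcripts run in transcript
orientation and are converted back for genomic output. Transcript↔genome
mapping is a bijection on exonic positions and is property-tested on random
transcript models.

An ORF runs from the most upstream in-frame AUG to the first in-frame stop
codon, one candidate per stop, with a minimum span of 27 nt *including* the
stop codon — i.e. nine codons, eight encoded residues. This convention
(rather than 27 nt of coding sequence) is configurable via `min_nt`.
Codons containing N are treated as neither start nor stop, and an ORF whose
span includes one is dropped rather than shifted to a later AUG. ORFs
truncated by the transcript end (no stop codon) are discarded. Non-AUG
starts are out of scope. Unstranded transcripts (some lincRNA catalogs)
are scanned on both strands.

Classification applies a fixed first-match order (annotated → pseudogene →
ncRNA → utr3 → utr5 → cds_overlap → other → lincRNA) over the members of
each (interval chain, peptide) group, then moves ORFs fully contained in
annotated CDS to `cds_overlap` unless a group member's transcript implies
`other`. "Canonical" coding transcripts are those whose annotated CDS
starts at the most upstream AUG for its stop; the pseudogene test accepts
either a transcript or a gene biotype containing "pseudogene". CDS overlap
anywhere uses a 1-bp minimum, strand-agnostic.

## Conservation features

Per-species coverage over an ORF counts aligned (non-gap) reference
positions; a species qualifies at ≥ 50 %. A frameshifting indel is any
deletion run over reference bases, or any insertion recorded in the
per-species insertion index, with length ≢ 0 (mod 3); indels are assessed
on the raw blocks before stitching so that stitching cannot mask them.

The selection score is a pluggable backend. `backend="table"` consumes
precomputed per-ORF scores (the supported path for real PhyloCSF output).
`backend="surrogate"` sums, over qualifying species and gap-free codon
columns, log₂ P_cod(e)/P_nc(e), where the event e classifies the species
codon against the reference codon directly (no ancestral reconstruction):
identical, synonymous, non-synonymous, or stop-introducing. The default
probability tables, P_cod = (0.55, 0.30, 0.14, 0.01) and
P_nc = (0.40, 0.20, 0.35, 0.05), are package defaults chosen so that
coding-like and neutral evolution separate; they are not fitted to any
biological dataset and are configurable.

Step profiles cover 50 nt centered on the first base of the start codon
(and of the stop codon), in spliced transcript coordinates, extending into
flanking genomic sequence past transcript ends. Windows clipped at a
contig edge are compared over the available bases and the distance scaled
by √(50/observed). The profile mean is taken base-wise over the positive
training set.

Ancestral conservation: a species "conserves" an ORF when its start and
stop codons are intact, splice-site dinucleotides (for spliced ORFs) match
the reference row, and no premature stop or frameshifting indel occurs.
The per-ORF MRCA of the conserving set (reference always included) is
located on the root-to-reference path; reported fractions are of ORFs
whose MRCA is at least as old as each ancestor, which is non-increasing
with age by clade nesting.

## Classifier

Features are whitened to zero mean and unit variance on the training data;
constant features get unit scale with a warning. The linear SVM
(scikit-learn `LinearSVC`, squared hinge) uses a regularization parameter
interpreted per-sample-average, so duplicating the training set leaves the
fitted model unchanged; the default C = 1.0 is a package choice. Error
rates are estimated from 100 resampling runs assigning each example to the
training side with probability 0.5; runs with an empty class are redrawn
and logged. ROC cutoffs minimize (FNR + FPR)/2 over the unique scores and
their midpoints, ties resolved to the smallest threshold.

## Overlap filter

Step 1 keeps annotated sORFs and predictions not intersecting (≥ 1 bp,
either strand by default) annotated coding exons whose frame-conservation
count reaches the species threshold. Step 2 removes predictions strictly
contained (genomic interval chains, same strand by default) in a longer
prediction that itself passed step 1; the family representative is the
longest ORF, ties broken by selection score. The filter is idempotent and
its output contains no contained pair — both verified as properties on
randomized prediction sets.

## Selection analysis

Length-adjusted scores are z-scores within length-percentile bins
(population SD; all-equal bins map to 0); bins under 20 members merge with
a neighbor. Conservation-matched controls come from the 20 % of the pool
with selection scores closest to zero, stratified-sampled on deciles of
the candidates' mean per-base conservation until a two-sided Mann–Whitney
test between candidate and control conservation gives P > 0.1 (at most
1,000 attempts; an empty stratum falls back to the whole restricted pool);
infeasible matching raises an error reporting the best P achieved.

dN/dS uses Nei–Gojobori equal-weight site counting: each codon position
contributes the fraction of its three single-nucleotide changes that are
synonymous; changes to stop codons count as non-synonymous; start and stop
codons are excluded from sites and SNP counts. SNPs on the minus strand,
in repeats, or with derived allele frequency < 1 % (when annotated) are
removed first; multi-allelic records are split. The "reciprocal χ²"
comparison tests the candidate's (non-syn, syn) SNP counts against
expectations from the control's per-site rates (one-sided for depletion)
and the control's counts against candidate-derived expectations (direction
flipped); the reported P is the larger of the two.

## Homology clustering

Directed hits qualify when sizes deviate ≤ 20 % (|Δ|/max), E < 10, and
PID_eff = PID·L_aln/L_query exceeds 30 + 70·e^(−(L_q+L_s)/20), each
directed hit tested with its own query length. Only mutual edges survive;
within-species components form paralog clusters; across species, cluster
pairs connect only as reciprocal best hits (best = maximum PID_eff over
member pairs, ties by lower E-value then lexicographic id); singletons are
dropped. Isomorphic clusters — identical multisets of (species, category)
labels — merge with a multiplicity count; the reporting rule keeps
clusters spanning ≥ 2 species with ≥ 1 non-annotated member. The internal
Smith–Waterman aligner (PAM30, gap open 9 / extend 1, small-database
Karlin–Altschul E-values) exists for fixtures and tests; production runs
consume external tabular hits.

## Translation and expression evidence

ORFscore: with F̄ the mean of the three frame counts (5′ ends per codon
position, first and last codon excluded), score = log₂(Σ(Fᵢ−F̄)²/F̄ + 1),
negated when frame 2 or 3 exceeds frame 1, and 0 with no reads. The
translation cutoff is 6; a dataset qualifies when the two-sample KS D
between annotated-sORF and negative-control scores is ≥ 0.55. Note the
score is bounded by log₂(2N+1) for N reads, so calling at cutoff 6
requires ≳ 100 reads per ORF at 80 % frame bias; the simulator's default
depth (120 reads/ORF) reflects the deep-coverage regime in which the
metric is usable. Metagene 5′ offsets are identifiable only mod 3 from
phasing; the absolute offset is taken from the initiation peak upstream of
annotated starts, and the simulator plants such a peak (10 % of reads).
Replicate samples are pooled before offset estimation.

Expression: FPKM rows with all values < 10⁻⁴ are dropped;
TPM = 10⁶·FPKM/ΣFPKM per sample (columns sum to 10⁶ afterwards); mean
expression averages non-zero TPM values; specificity is the normalized
information content IC = (1/log₂N)·Σ rₜ log₂(rₜN) over
rₜ = log₂(TPMₜ+1)/Σₛ log₂(TPMₛ+1), 0 for uniform use and 1 for
single-sample expression.

## 3′UTR sORF diagnostics

The conservation step at a stop codon is mean(25 nt inside) − mean(25 nt
outside); the stop codon itself is excluded from both windows (a
configurable convention). Distances, frame offsets, and intervening stop
counts are computed in spliced transcript coordinates, making them
invariant under intron insertion between CDS and dORF (property-tested).
Readthrough candidates match on exact genomic stop-codon coordinates.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes.
The default species tree has five leaves with reference-to-species
divergences of 0.10–0.33 substitutions/site — roughly the
primate-to-placental-mammal range where frame conservation and codon
substitution patterns are informative. Codon substitution is simulated per
branch with a simple two-rate model (synonymous 0.8/codon,
non-synonymous 0.12/codon per unit branch length) and no rate
heterogeneity across sites; branches on the root-to-reference path do not
mutate, keeping the reference row identical to the simulated genome.
Neutral loci substitute at 1.0/site and receive 1–2-nt frameshifting
indels inside the ORF in half the species; pseudogene-like loci are
coding-derived with planted nonsense or frameshift events. Coding loci get
a conservation-track step (0.85 inside the ORF, 0.2 in the flanks);
neutral loci a flat 0.3 track.

SNPs arise independently per possible single-nucleotide change, synonymous
changes at a base rate and non-synonymous at ω times that rate, calibrated
so the common (DAF ≥ 1 %) variants hit the configured density (default
20/kb); rare variants are generated on top at 10 % of the common rate as
filter fodder. At this density a 10-kb aggregate identifies ω = 0.2 to
roughly ±0.03 (1 SD), so the ω = 1 control — whose relative precision is
worse because synonymous SNPs are the minority — is assessed on a 100-kb
aggregate at the same density.

Planted peptide families are near-identical within a family (≥ 90 %
identity) and rejection-sampled so that no chance local alignment between
families approaches the clustering cutoff; this makes exact recovery a
well-posed target.

**What passing tests show — and don't.** The fixtures establish that each
statistic recovers its planted parameter and that the pipeline's rules
compose correctly. They do not capture alignment errors, assembly gaps,
lineage-specific rate variation, GC/codon-usage heterogeneity,
ribosome-profiling library biases beyond a single frame-bias parameter, or
annotation errors — so synthetic error rates are best-case, not estimates
of performance on real genomes. For real data, the surrogate selection
score should be replaced by PhyloCSF scores via the table backend.

## Known limitations

- The surrogate score compares each species to the reference pairwise and
  ignores phylogenetic correlation between species.
- Stop codons split across splice junctions are handled by the spliced
  interval chain, but the reported genomic stop-codon interval assumes the
  stop lies within one exon.
- The overlap filter rejects sORFs overlapping longer ORFs in alternative
  reading frames by design; genuinely overlapping coding units are lost.
- `select_matched_controls` uses sampling with replacement when a stratum
  is smaller than its demand, which can repeat control ORFs.
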