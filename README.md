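# smorf

Discovery and analysis of conserved small open reading frames (sORFs) in
annotated transcriptomes.

Transcripts and transcript regions annotated as non-coding — lincRNAs,
5′UTRs, 3′UTRs — frequently contain short AUG-initiated ORFs, and a subset
of these encode functional micropeptides. Because short ORFs arise by
chance in any nucleotide sequence, sequence statistics alone cannot
separate real coding sORFs from noise. `smorf` implements a comparative
genomics pipeline that isolates the conservation signatures characteristic
of purifying selection on the *encoded peptide* rather than on the
nucleotide sequence:

1. **ORF scanning and classification.** Spliced transcripts are scanned
   for ORFs from the most upstream AUG per in-frame stop codon (minimum
   span 27 nt including the stop). Identical ORFs across isoforms are
   grouped and classified by location: `annotated`, `pseudogene`, `ncRNA`,
   `utr3`, `utr5`, `cds_overlap`, `other`, or `lincRNA`.
2. **Conservation features.** From a multiple species alignment, each ORF
   receives four features: a codon-level selection score (a pluggable slot
   for PhyloCSF output, with a built-in log-odds surrogate that classifies
   each species codon as identical / synonymous / non-synonymous /
   stop-introducing), the number of species without frameshifting indels
   (indel length ≢ 0 mod 3) at ≥ 50 % coverage, and the Euclidean
   distances of the 50-nt phastCons-style profiles around start and stop
   codons from the positive-set mean.
3. **SVM prediction.** A linear SVM over the whitened features, trained on
   curated annotated small proteins (≤ 101 codons, positive selection
   score) versus sORFs on classical ncRNAs. Error rates come from 100
   50/50 resampling runs; score cutoffs from the minimum-average-error
   point of the ROC curve.
4. **Overlap filter.** Predictions overlapping frame-conserved annotated
   coding exons, or contained in a longer predicted ORF, are removed so
   each conservation signal is assigned to one candidate.
5. **Downstream evidence.** SNP-based dN/dS with Nei–Gojobori site counts
   and reciprocal one-sided χ² tests; ancestral conservation (MRCA of the
   species conserving start, stop, splice sites, frame); cross-species
   homology clustering with the length-aware cutoff
   PID_eff = PID·L_aln/L_query > 30 + 70·e^(−(L_q+L_s)/20) and
   reciprocal-best-hit cluster linking; amino-acid/codon usage and KL codon
   bias; motif scanning in disordered regions; ORFscore translation calling
   from ribosome-profiling 5′ ends
   (score = ±log2(Σ(Fᵢ−F̄)²/F̄ + 1), cutoff 6, dataset gate KS D ≥ 0.55);
   TPM expression and tissue-specificity information content
   IC = (1/log₂N)·Σ rₜ·log₂(rₜN) with rₜ = log₂(TPMₜ+1)/Σₛlog₂(TPMₛ+1);
   and 3′UTR-sORF diagnostics against stop-codon readthrough.

A first-class synthetic-data module generates every input format the
pipeline consumes (FASTA, GTF, MAF, bedGraph, VCF, BED, FPKM tables) with
known ground truth — coding-like loci under synonymous-biased codon
substitution, neutral loci with frameshifting indels, pseudogene-like
loci with nonsense events — so the whole pipeline is testable end to end
without any external downloads.

## Worked example

```python
import numpy as np
from smorf.synthetic_data import SimulationConfig, simulate_locus_set
from smorf import orf_catalog as oc, conservation_features as cf, \
    svm_classifier as svm

cfg = SimulationConfig(seed=4, n_annotated=40, n_novel=10,
                       n_neutral_ncrna=40, n_neutral_linc=5, n_pseudogene=5)
bundle = simulate_locus_set(cfg)

orfs = oc.scan_orfs(bundle.transcripts, bundle.genome)
index = oc.AnnotationIndex(bundle.transcripts, bundle.genome)
oc.classify_all(orfs, index)
```

Scanning this 100-locus bundle finds 143 ORF groups:

```
ORF groups by category: {'annotated': 40, 'cds_overlap': 9, 'other': 9,
                         'lincRNA': 24, 'ncRNA': 55, 'pseudogene': 6}
```

(The extra groups beyond the 100 planted ORFs are chance ORFs in UTRs and
alternative frames — exactly the background the classifier must reject.)
Extracting features for the planted loci and cross-validating the SVM:

```
mean selection score: coding 60.0, neutral -22.1
mean frame-conserved species: coding 4.00, neutral 2.09
cross-validated FNR 0.000 +- 0.000, FPR 0.000 +- 0.000
```

Coding-like loci score strongly positive (synonymous substitutions
outweigh non-synonymous ones) and keep their frame in all four aligned
species; neutral loci score negative and lose the frame in about half.
At this separation the classifier makes no held-out errors.

The same steps are available from the shell:

```bash
smorf simulate --seed 4 --out fixtures/
smorf scan --gtf fixtures/annotation.gtf --fasta fixtures/genome.fa \
      --out orfs.bed12 --table orfs.tsv
smorf features --orfs orfs.tsv --maf fixtures/alignment.maf \
      --track fixtures/track.bedGraph --out features.tsv
smorf train --features features.tsv --pos pos.txt --neg neg.txt \
      --model model.json
smorf predict --model model.json --features features.tsv --out pred.tsv
```

plus `smorf filter`, `smorf dnds`, `smorf cluster`, `smorf ribo`, and
`smorf expr` for the downstream analyses.

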