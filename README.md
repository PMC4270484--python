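# orthopeaks

Comparative-epigenomics toolkit for asking how transcription-factor (TF)
occupancy and chromatin structure diverge between two species — modeled
on the human/mouse comparison of erythroid (red-blood-cell) precursors,
where master regulators such as GATA1, TAL1, KLF1 and NFE2 drive
differentiation in morphologically identical but transcriptionally
divergent cells.

It is written for genomicists who have, for each species, TF ChIP-seq
peaks with summits and read-count scores, a whole-genome chain alignment,
ortholog-paired gene annotations, histone-mark tag files with input
controls, a chromatin-state segmentation, and stage-resolved RNA-seq
(FPKM) tables — and who want, with no external services, the full
analysis chain:

1. **Cross-species mapping** (`chain_lift`) — a reimplementation of
   liftOver semantics over UCSC chain files: an interval maps when at
   least a fraction *minMatch* (default 0.10) of its bases fall in
   aligned blocks of a single best chain; hits split across two chains
   are rejected (one:one matching). Peaks are mapped as narrow summit
   windows (summit ± 50 bp).
2. **Conservation classification** (`peak_conservation`) — each mapped
   source peak is *conserved* (its lifted window intersects a
   destination peak) or *lost*; destination peaks within ± 5 kb of a
   lost site are *compensatory*; remaining destination peaks are
   *gained*, and the top 10 % of gained peaks by mapped-read score are
   *strongly gained*. Rates use only successfully mapped peaks as the
   denominator.
3. **Combinatorial co-occupancy** (`cooccupancy`) — single-linkage
   clustering of summits across a TF panel at ± 1000 bp yields candidate
   cis-regulatory modules (CRMs; 2^k − 1 combinatorial groups); mapping
   them across species gives a row-stochastic transfer matrix whose
   diagonal is group retention, plus extraction of fully-conserved CRMs
   and their nearest-TSS gene assignment.
4. **Enrichment statistics** (`enrichment_stats`) — a Genomic
   Association Tester-style permutation test (segment-length-preserving
   uniform placement in a workspace, add-one p-values), chromatin-state
   overlap folds, 2×2 occupancy odds ratios with Haldane–Anscombe
   correction, and Mann–Whitney comparisons.
5. **Signal quantification** (`signal_quant`) — 200 bp fragment
   extension, reads-per-million normalization with input subtraction
   (floored at 0), promoter matrices of log2(1 + mean signal) around the
   TSS, metagene profiles, and H3K4me3/H3K27me3 promoter classification.
6. **Expression modeling** (`expression_model`) — per-mark quantile
   normalization across species, L1-penalized (lasso) regression of
   log2(1 + FPKM) on promoter marks with K-fold cross-validation and the
   one-standard-error rule, a consensus model pooled over both species,
   and a difference model: applying the consensus coefficients to
   Δmarks = X_h − X_m predicts Δexpression = y_h − y_m.
7. **Synthetic data** (`synthetic_data`) — a first-class generator of
   paired "genomes" joined by a chain, ortholog gene pairs, peak sets
   with planted conservation/compensatory/gain rates, tags whose pileup
   recovers the planted promoter intensities, expression from a planted
   linear model (y = α + Xβ + ε, exported as FPKM = 2^y − 1), and a
   state segmentation with a planted active-state fold.

The model at the core is the penalized regression

    y_g = α + Σ_m β_m X_gm + ε_g,   ε_g ~ N(0, σ²),

with y the log2(1 + FPKM) expression of gene *g* and X_gm the
log2-scaled input-subtracted RPM of mark *m* in the promoter
(TSS ± 2 kb); β̂ minimizes ‖y − α − Xβ‖² / 2n + λ‖β‖₁ with λ chosen by
cross-validation at one standard error above the minimum.

## Worked example

```python
import numpy as np
from orthopeaks import synthetic_data as sd, peak_conservation as pc

cfg = sd.SyntheticConfig()            # 2 chromosomes, planted rates
rng = np.random.default_rng(1)
genome = sd.generate_genome_pair(cfg, rng)
peaks = sd.generate_peaks(cfg, genome, rng)

for tf in ("GATA1", "KLF1"):
    ps = peaks[tf]
    cls = pc.classify_source_peaks(ps.src_peaks, ps.dst_peaks, genome.chains)
    s = cls.summary
    print(tf, round(s.rate_conserved, 3), round(s.rate_compensatory, 3))
```

prints

```
GATA1 0.249 0.262
KLF1 0.602 0.203
```

i.e. with a planted conservation rate of 0.25 for GATA1 (0.60 for KLF1)
and a planted compensatory fraction of 0.25 of lost sites, the classifier
recovers 24.9 % (60.2 %) conservation and a 26.2 % (20.3 %) compensatory
fraction — binomial sampling noise around the planted truth.

The full pipeline runs from a JSON config (or defaults):

```
orthopeaks run --config run.json       # simulate -> ... -> report
orthopeaks simulate --out fixture/ --seed 7
orthopeaks lift --chain a.chain --bed peaks.bed --out lifted.bed
```

`run` writes a bundle of figure-analog tables (conservation summaries,
co-occupancy transfer matrix, conserved CRMs with gene assignments,
state-enrichment folds per conservation category, consensus-model
coefficients and R², difference-model predictions, expression-by-category
summaries) plus a validated `summary.json`.

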