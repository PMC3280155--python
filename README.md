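# promstruct

Analysis of DNA structural properties of core promoters. The package
converts promoter-window sequences (TSS-relative −200..+50, 251 nt) into
thirteen smoothed structural profiles (duplex free energy, stacking energy,
DNA denaturation, duplex disrupt energy, protein deformation, Z-DNA,
DNA-bending stiffness, A-philicity, nucleosome position, propeller twist,
protein-DNA twist, B-DNA twist, bendability), assembles them into a
normalized 13×251-dimension feature matrix, selects discriminative
dimensions with filter criteria (information gain, chi-square, ReliefF,
CFS) or a genetic-algorithm wrapper (SVM / kNN fitness), and evaluates
promoter-vs-non-promoter classification with sensitivity, precision-style
specificity, F-measure and ROC score.

A synthetic-data module stands in for the original TSS databases: negative
sets are sampled from a first-order Markov model that preserves
dinucleotide frequencies, and positive sets are background chains with a
TATA-like box planted near −30 and an Inr-like element at the TSS.

## Library overview

| module | contents |
| --- | --- |
| `promstruct.profiles` | `PropertyScale`, `load_scale`, `raw_profile`, `smooth`, `convert_sequence`, `average_profile`; 13 bundled scale tables |
| `promstruct.datasets` | FASTA/BED I/O, `TssRecord`, strand-aware `extract_window(s)`, `LabeledSequenceSet` |
| `promstruct.synthetic` | `fit_markov1`, `generate_background`, `PromoterSimConfig`, `generate_promoters` |
| `promstruct.features` | `build_matrix` → `FeatureMatrix` (13×251 dims), `dims_for_feature` |
| `promstruct.selection_filter` | `discretize_mdl`, `ig_scores`, `chi2_scores`, `relieff_scores`, `cfs_merit`, `cfs_select`, `top_k` |
| `promstruct.selection_wrapper` | bitstring `genetic_search`, `wrapper_select` (CV-accuracy fitness) |
| `promstruct.evaluation` | `metrics_from_counts`, `roc_score`, `cross_validate`, `feature_ratio`, `correlate_features`, `match_tss` |

Conventions: BED input is 0-based half-open (TSS = `start` on `+`,
`end−1` on `−`); the window is −200..+50 inclusive; this codebase keeps
the source study's metric naming, where "specificity" = TP/(TP+FP)
(elsewhere called precision).

## CLI

```bash
# simulate positives (planted TATA/Inr) + Markov background negatives
promstruct simulate --n 500 --seed 1 --out-prefix scratch/sim

# extract strand-aware promoter windows from a genome + BED
promstruct extract-windows --genome genome.fa --bed tss.bed --out windows.fa

# averaged structural profile of one feature
promstruct profile --fasta scratch/sim.promoters.fa \
    --feature dna_denaturation --average --out denat.tsv

# filter selection (ig | chi | relieff | cfs)
promstruct select --positives scratch/sim.promoters.fa \
    --negatives scratch/sim.background.fa --method ig \
    --sizes 100,200,300,400,500 --out-prefix scratch/sel

# GA wrapper selection
promstruct wrapper --positives scratch/sim.promoters.fa \
    --negatives scratch/sim.background.fa --classifier svm \
    --out-prefix scratch/wrap

# cross-validated metrics for a subset
promstruct evaluate --positives scratch/sim.promoters.fa \
    --negatives scratch/sim.background.fa --subset scratch/sel.ig.300.tsv \
    --out metrics.json

# per-feature composition of a selected subset
promstruct feature-ratio --positives scratch/sim.promoters.fa \
    --negatives scratch/sim.background.fa --subset scratch/sel.ig.300.tsv
```

## Scale tables

The conversion schemas under `src/promstruct/data/scales/` are plain TSV
(`kmer<TAB>value`) transcribed from the published biophysical literature
compilations (best effort; a few tables are approximate). The code is
scale-agnostic — drop in corrected tables or pass your own via
`promstruct.load_scale` without code changes.
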