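# deepgp

Disease–gene prioritization from GWAS and eQTL summary statistics.

`deepgp` ranks candidate genes for a panel of diseases (the motivating
setting is five endocrine diseases: Graves' disease, type 1 and type 2
diabetes mellitus, polycystic ovary syndrome, and IGF-I deficiency) by
combining three sources of evidence:

1. **Summary-statistic gene features.** SNP associations are mapped onto
   genes by genomic position. For each gene, each disease and each omics
   layer (GWAS phenotype associations; eQTL expression associations, which
   mitigate linkage-disequilibrium ambiguity by crediting the regulated gene
   rather than the nearest one), the feature is the vector of the *k* = 5
   smallest p-values, sorted ascending and padded with 1 — a 2 × 5 × 5 block
   per gene for a five-disease panel.
2. **Network smoothing by graph convolution.** With gene-feature matrix
   *X* ∈ ℝ^(N×F) and the weighted gene-interaction adjacency *A* (HumanNet-style
   edge scores), features are propagated through the self-looped,
   symmetrically normalized operator

       L = D^{-1/2} (A + I) D^{-1/2},  H^{(l+1)} = σ(L H^{(l)} W^{(l)}),  H^(0) = X,

   so each gene's evidence is shared with its interaction neighborhood. By
   default one layer's weight matrix W (50 × 50) is trained jointly with the
   classifier; a deterministic `fixed` mode (W = I, no nonlinearity) gives
   pure network smoothing.
3. **CNN pair classification.** A disease–gene pair becomes a 3-channel
   5 × 5 image — the gene's GWAS block, its eQTL block, and the target
   disease's similarity row (from a precomputed disease–disease similarity
   matrix) tiled across rows — scored by a small CNN (tanh convolutions,
   ceil-mode 2 × 2 max-pooling, dense layers, sigmoid output) trained with
   binary cross-entropy on curated positives versus an equal number of
   negatives sampled uniformly from the unlabeled complement.

Evaluation is stratified 10-fold cross-validation reporting per-fold AUC and
AUPR; screening of unlabeled pairs uses a score threshold (default 0.5).
A synthetic-data module generates complete, referentially consistent input
bundles with planted causal signal, so the whole pipeline is testable
without any external downloads.

**Known protocol caveat:** negatives are sampled once on the full dataset
*before* fold splitting, and the balanced sample is global rather than
per-disease. Both follow the original protocol; they let dataset-level
quirks (realized per-disease imbalance, genes recurring across folds) shift
the null cross-validation AUC a few points away from 0.5. See
`docs/methods.md`.

## Worked example

```bash
# 1. generate a 500-gene, 5-disease bundle with planted signal
deepgp simulate bundle/ --seed 7

# 2. cross-validate the full pipeline
deepgp cv bundle/ -o results/cv.tsv --seed 7

# 3. train on all labeled pairs, then screen the unlabeled pairs
deepgp train bundle/ -o results/model.npz --seed 7
deepgp predict results/model.npz -o results/predictions/
```

The `cv` stage logs (stderr):

```
[deepgp:cv] 500 genes retained, 337 curated positives, config 78a6da923f27
[deepgp:cv] mean AUC 0.9841, mean AUPR 0.9883, wrote results/cv.tsv in 109.6s
```

and `results/cv.tsv` holds one AUC/AUPR row per fold plus a `mean` summary
row. A mean AUC of ~0.98 on this planted panel means held-out curated
disease–gene pairs are almost always ranked above sampled negatives; the
same protocol on a signal-free bundle (`deepgp simulate --null`) stays near
chance (mean AUC ≈ 0.45). `predict` writes `scores.tsv` (all unlabeled pairs,
sorted by disease then descending score), `screened.tsv` (pairs with score
above the threshold), and `screening_summary.tsv` (per-disease counts).

Every stage accepts `-c config.yaml` plus repeatable `-O key=value`
overrides; unknown keys are rejected. All randomness flows from `--seed`, so
identical invocations produce byte-identical outputs.

## Library use

```python
import deepgp

bundle = deepgp.generate_bundle(deepgp.SyntheticConfig(seed=7))
cfg = deepgp.RunConfig(seed=7)
inputs = deepgp.prepare_inputs(bundle.tables(), cfg)
result = deepgp.cross_validate(inputs, cfg)
print(result.mean_auc, result.mean_aupr)
```

Real data enters through `deepgp.load_bundle(directory)`: six TSV tables
(gene annotations; GWAS and eQTL SNP tables; weighted edge list; curated
disease–gene associations; square labeled disease-similarity matrix) in one
harmonized gene/disease namespace — see `src/deepgp/io.py` for the exact
dialects.

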