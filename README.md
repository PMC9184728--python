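# dicpipe

`dicpipe` is an analysis pipeline for **decreased intragenic cohesin sites
(DICs)**: cohesin (Rad21) peaks inside the bodies of transcriptionally
responsive genes that lose binding when transcription is stimulated (e.g.
estradiol-treated MCF-7 cells).  It implements the full analysis chain around
this phenomenon — quantitative two-condition peak comparison, the
DIC-extraction cascade, Hi-C contact-map metrics, chromatin-loop statistics,
and a machine-learning framework for predicting DICs from genomic features —
together with a synthetic-data generator that plants every signal the
pipeline is supposed to recover, so the whole analysis is testable without
any external sequencing data.

## The analysis in brief

**Differential binding (MA normalization).**  For each peak matched across
conditions, `A = ½(log₂ d₁ + log₂ d₂)` is the average signal strength and
`M = log₂(d₂/d₁)` the log fold change of normalized read densities.  A robust
(Theil–Sen) linear trend `M = a + b·A` fitted on common peaks absorbs the
condition-wide efficiency imbalance; the residual is the *normalized M value*.
Peaks with `M > 0.5` are increased, `M < −0.5` decreased.

**DIC extraction.**  A cohesin site is a DIC iff it (1) is ≤ 3 kb wide,
(2) has normalized `M < −0.5`, (3) lies in an *intragenic region* — the gene
body minus 10-kb flanks around TSS and TES, for genes longer than 20 kb — and
(4) its host gene is responsive (elongation-signal ratio > 1.2 between
conditions, validated by an expression increase).  DICs are split into
low-CTCF (LC) and high-CTCF (HC) subtypes by two-component clustering of
log CTCF density after dropping sites with very low Rad21 signal.

**Hi-C metrics.**  Per-bin distal-to-local ratio `DLR = log₂(distal/local)`
and inter-chromosomal fraction `ICF = inter/(inter+intra)`; their
between-condition differences (ΔDLR, ΔICF; positive = de-compaction),
the insulation score (log₂ of the off-diagonal square mean over its
distance-matched expectation, with boundaries at local minima), and aggregate
peak analysis (APA; score = aggregate center over the lower-left corner
block, condition comparison by paired t test on per-pair central enrichment).

**Statistics.**  Two-sided Fisher exact tests for loop occurrence,
Mann–Whitney U (exact for small samples), paired t, upper-tail hypergeometric
overlap, and Benjamini–Hochberg adjustment.

**Machine learning.**  Sites × features matrices (binary co-localization +
z-scored continuous columns), k-means clustering, SMOTE over-sampling of the
rare DIC class, logistic regression `P(Y=1|X) = 1/(1+e^{−(β₀+Σβ_jX_j)})`
evaluated on chromosome-held-out sites, signed-coefficient importance, and
elastic-net feature selection, loss
`RSS/(2n) + λ((1−α)/2·Σβ² + α·Σ|β|)` with λ chosen by cross-validation,
followed by univariate fits on the survivors.

## Worked example

```bash
dicpipe run --seed 1 --out runs/demo
```

simulates the default scene (2 chromosomes × 20 Mb, 300 genes, ~3,000
cohesin sites, 100 planted DICs at fold change 0.5) and runs every stage.
It prints:

```json
{
  "n_sites": 3000,
  "n_dics": 99,
  "n_hc": 25,
  "n_lc": 74,
  "ma_intercept": -0.13948429626270034,
  "apa_t": 3.592843202591594,
  "apa_p": 0.0005228580788016823,
  "apa_score_a": 6.0105669823621435,
  "apa_score_b": 1.3463914979090545,
  "test_auroc": 0.7850307587149692
}
```

99 of the 100 planted DICs are recovered (none spurious), split into 25
high-CTCF and 74 low-CTCF sites; loop pixels anchored at DICs are ~6-fold
enriched in the control map and drop to background after the stimulated-
condition loops are removed (paired t, p ≈ 5 × 10⁻⁴); a logistic model
trained on co-binding features alone separates DICs from other cohesin sites
on the held-out chromosome.  `runs/demo/` contains the per-stage tables
(`diffpeaks.tsv`, `site_calls.tsv`, `dics.bed`, `delta_dlr.tsv`,
`insulation.tsv`, `features.tsv`) plus a manifest with checksums.

Library use mirrors the CLI:

```python
import dicpipe
from dicpipe import pipeline

cfg = pipeline.validate_config({"seed": 1})
scene = dicpipe.simulate_scene(dicpipe.SimulationParams(seed=1))
diff = pipeline.run_diffpeaks(scene, cfg)
calls = pipeline.run_dic_extraction(scene, diff, cfg)
print(calls["is_dic"].sum())   # 99
```

## Layout

```
src/dicpipe/
  formats.py     BED/BEDPE/TSV/contact-map readers and writers
  synthio.py     synthetic scenes with planted ground truth
  diffpeaks.py   MA normalization and change classification
  sitecalls.py   intragenic regions, responsive genes, DIC calls, LC/HC
  hicmetrics.py  balancing, DLR/ICF, insulation score, APA
  loopstats.py   loop occurrence, anchor annotation, statistical tests
  mlfeat.py      feature matrices, k-means, SMOTE, logistic / elastic net
  pipeline.py    config validation and staged orchestration
  cli.py         the `dicpipe` console script
```

See `docs/methods.md` for the modelling choices and their rationale.
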