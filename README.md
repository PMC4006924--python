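# sepsiskit

Tools for asking whether two experimental sepsis models elicit the same
blood-leukocyte transcriptome response — and for quantifying how far any
septic sample's expression profile has moved from healthy controls.

The motivating setting is the comparison of two low-lethality murine
models of polymicrobial intra-abdominal sepsis: cecal ligation and
puncture (CLP, here "model A") versus intraperitoneal cecal slurry (CS,
"model B"), profiled on microarrays at 2 hours, 1 day and 3 days after
onset alongside healthy controls. The package is equally usable for any
two-condition, multi-timepoint expression design, and ships a
synthetic-data generator with known ground truth so that every stage of
the analysis can be validated end to end.

## What it computes

Given a log2 expression matrix *X* (probe sets × samples), a sample
sheet (class ∈ {control, modelA, modelB}, timepoint) and a probe→gene
map:

- **Unsupervised selection** — keep probes with coefficient of
  variation sd/mean > 0.5 on the linear (anti-logged) intensity scale.
- **Supervised selection** — one-way F-test across the three classes
  (or across every (model, timepoint) cell), keep probes with raw
  p < 0.001; probe sets collapse to genes (a gene is significant if any
  of its probe sets is), with overlap accounting between the models.
- **Fold changes** — per probe, d = mean(group) − mean(control) in log2
  units, reported with the reciprocal signed-fold convention
  (d = −1 → fold −2, never 0.5).
- **Class prediction** — leave-one-out cross-validation of a
  nearest-centroid classifier on standardized log2 values, with gene
  selection re-run inside each fold, and a Monte-Carlo permutation null:
  p = (1 + #{null rate ≤ observed}) / (B + 1).
- **Concordance** — per timepoint, Pearson r between the two models'
  mean log2 change vectors over the union of their significant probes;
  plus the "maximum-change" r, correlating each probe's
  largest-magnitude change across timepoints (sign retained).
- **DFR (distance from reference)** — per sample,
  D = Σᵢ (eᵢ − Mᵢ)² / Vᵢ over the significant probes, where Mᵢ, Vᵢ are
  the control mean and variance; reported as the single natural-log
  metric ln D. Under the null E[D/G] = (1 + 1/n)(n−1)/(n−3) for G
  probes and n controls (≈1.41 at n = 10).
- **Gene-set statistics** — Fisher exact over-representation reported
  as −log10 p (the p = 0.05 line is 1.3), and for direction-annotated
  sets the activation Z = (N₊ − N₋)/√N over members changing at least
  two-fold, with |Z| ≥ 2 called significant.

## Worked example

`examples/02_concordance.py` generates a dataset whose between-model
effect correlation dial is set to 0.6 / 0.4 / −0.3 at 2 h / 1 d / 3 d,
then re-estimates those correlations from the expression data alone:

```
                r    p  n_probes
timepoint
2h         0.5846  0.0      3006
1d         0.3792  0.0      3006
3d        -0.2992  0.0      3006
max-change r = 0.161 (r^2 = 0.026)
generator dial: {'2h': 0.6, '1d': 0.4, '3d': -0.3} | realized: {'2h': 0.584, '1d': 0.38, '3d': -0.298}
```

Each per-timepoint r recovers the dial within sampling error — the
pattern of strong early concordance decaying to an inverse correlation
by day 3 — and the max-change r lands between the per-timepoint
extremes. `examples/04_class_prediction.py` shows the class-prediction
side on clearly structured data:

```
observed LOOCV misclassification: 0.000
null rates: mean 0.674, min 0.233
permutation p = 0.001  (999 permutations)
```

The observed rate of 0 against a null centred on 2/3 (three balanced
classes) gives the floor p-value 1/(B+1): class membership is
recoverable from expression far better than chance. The other examples
cover selection and overlap accounting (01), DFR scoring and model
ordering (03), gene-set statistics (05) and the full file-based
pipeline (06).

## Command line

A thin CLI wraps the library: `sepsiskit simulate | select | compare |
dfr | predict | enrich | run`. `sepsiskit run --config config.yaml`
executes every stage and writes a report bundle (selection tables,
overlap counts, concordance report, DFR tables, prediction calls,
enrichment table, heat-map orderings) plus a `manifest.json` carrying
the config hash and seed; reruns are bit-identical.

## Input formats

- expression: TSV, first column `probe_id`, one column per sample,
  log2 intensities, no missing values;
- samples: CSV with `sample_id, class_label, timepoint` (timepoint
  empty for controls); free-text labels such as CLP/CS map onto
  modelA/modelB via a configurable class map;
- probes: TSV with `probe_id, gene_symbol`;
- gene sets: GMT, with an optional direction dialect — a member written
  `Il6|+1` or `Socs3|-1` carries its expected regulation sign (within a
  set, either all members are directed or none is).

See `docs/methods.md` for the statistical background, parameter
defaults and known limitations.
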