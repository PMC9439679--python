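# loopdelta

Differential chromatin-architecture analysis on binned two-condition Hi-C
contact maps: loop calling with common/group-specific classification, A/B
compartment switch detection, insulation-score TAD analysis, and integration
of promoter-anchored loops with differential-expression classes and ChIP
peaks — including dot/TSS pile-ups with random-shift distance normalization
and one-sided promoter-stripe scoring.

Everything is exercisable offline on synthetic contact maps with planted
ground truth (power-law decay, compartment checkerboard, TAD blocks, focal
dots, strand-oriented stripes, matched DE gene table and peak set), so every
stage can be scored against known structure.

## Layout

| module | role |
| --- | --- |
| `loopdelta.simulate` | two-condition synthetic Hi-C generator with planted truth |
| `loopdelta.matrixio` | bin-table/COO matrix model, BEDPE/narrowPeak/bedGraph/gene-TSV I/O, iterative-correction balancing, coarsening |
| `loopdelta.compartments` | O/E, correlation-matrix eigenvector 1, activity-based sign fixing, AA/AB/BA/BB switch classification (delta > 1.5 on standardized tracks) |
| `loopdelta.domains` | diamond insulation score, boundary calling, TADs, aggregate-TAD maps, insulation similarity/PCA |
| `loopdelta.loopcall` | spline distance prior, bias-corrected binomial loop test, BH q-values (loops at q < 0.01), differential classes with a loose q < 0.1 secondary cutoff |
| `loopdelta.integrate` | DEG classification (FDR 0.05 / \|logFC\| 0.58 / stable 0.38), promoter (TSS ± 2 kb) loop and peak annotation, stratified loop scores, pile-ups and stripe scores |
| `loopdelta.pipeline` / `loopdelta.cli` | end-to-end orchestration with a YAML config and run manifest |

All coordinates are 0-based half-open. Matrices are stored as plain-text
bin tables plus upper-triangle COO TSVs.

## CLI

```sh
loopdelta run --seed 1 --outdir out/              # full synthetic pipeline
loopdelta simulate --config cfg.yaml --outdir out # single stage (+ deps)
loopdelta loops --seed 2 --outdir out             # simulate+balance+loops
```

The default configuration reproduces the analysis thresholds end to end
(loop q < 0.01 / loose q < 0.1, compartment delta > 1.5, promoter ± 2 kb,
DEG FDR 0.05 with logFC 0.58 / stable 0.38). Any stage parameter can be
overridden from a YAML file; unknown keys are rejected and every effective
parameter is echoed into `manifest.json`.

```yaml
# cfg.yaml
simulate:
  chrom_length_bp: 20000000
  depth: 20000000
loops:
  q_call: 0.01
  q_loose: 0.1
```

Exit codes: 0 success, 1 user error, 2 internal error.

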