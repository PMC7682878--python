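# splitfp

Quantitative analysis of split fluorescent protein (split-FP)
complementation: an equilibrium binding model whose log-log slope reads
out the effective K_D, the flow-cytometry pipeline that estimates that
slope from single-cell data, and the microscopy pipeline that quantifies
signal amplification from tandem FP_11 tags.  A synthetic-data module
generates cytometry event tables and imaging fields with known ground
truth, so every stage is testable end to end without wet-lab inputs.

Intended users: protein engineers benchmarking split-FP variants and
imaging groups quantifying tag amplification, as well as anyone needing a
reproducible, scriptable re-implementation of the standard gating +
slope-fit and particle-analysis recipes.

## The science in brief

A split FP reconstitutes fluorescence when its FP_1-10 fragment binds an
FP_11 peptide tag: A + B ⇌ C with dissociation constant K_D.  At
equilibrium the complemented concentration is

    C = 2AB / (A + B + K_D + √((A + B + K_D)² − 4AB)),

the root of (A−C)(B−C) = K_D·C.  Across a transiently transfected
population in which A and B co-vary in proportion and span decades, the
slope of log10(complemented signal) versus log10(expression reporter) is
**2** when K_D far exceeds cellular concentrations (C ∝ AB) and falls to
**1** as complementation saturates (C ∝ min(A, B)).  After rescaling by a
full-length control (an unsplit FP co-produced with the reporter, slope
≈ 1 by construction), the fitted slope is an instrument-independent
measure of complementation efficiency.

For a target carrying n tandem FP_11 copies sharing one FP_1-10 pool, the
free-fragment balance a + n·b·a/(a+K_D) = a_total predicts per-molecule
amplification in [1, n) — strictly sub-linear for any finite pool.  The
imaging pipeline measures this as the fold change of per-field median
nuclear intensities (1x vs 5x tags) with a one-sided Welch t-test.

## Worked example

The numbered scripts under `analysis/` are narrative drivers over the
library; each prints what it found and writes tables under `results/`.

```bash
$ python analysis/02_flow_slope_recovery.py
K_D =   0.0001 x median: pipeline 1.002  model 1.001  (diff +0.001)
K_D =     0.01 x median: pipeline 1.050  model 1.036  (diff +0.014)
K_D =      0.1 x median: pipeline 1.167  model 1.157  (diff +0.011)
K_D =        1 x median: pipeline 1.401  model 1.407  (diff -0.006)
K_D =       10 x median: pipeline 1.686  model 1.701  (diff -0.016)
K_D =      100 x median: pipeline 1.888  model 1.908  (diff -0.020)
K_D =    10000 x median: pipeline 1.982  model 1.998  (diff -0.016)
largest |pipeline - model| discrepancy: 0.020
```

Each line simulates 20,000 co-transfected cells at the given K_D (as a
multiple of the median fragment concentration), runs the complete event
pipeline — saturation filter, density scatter gate, singlet gate, log10
transform, untransfected thresholds, control rescaling, OLS — and
compares the rescaled slope with the closed-form model: the pipeline
recovers the theory across six decades of affinity, sweeping slope 1
(saturated complementation) to slope 2 (weak binding).

```bash
$ python analysis/03_tandem_amplification.py
model: 5x/1x fold vs FP_1-10 pool (b_tags=1, kd=1):
  pool 0.1 -> 1.70;  pool 1000 -> 5.00 (approaches 5 only for unlimited FP_1-10)
experiment: estimated fold 2.42 (true 2.3), one-sided Welch p = 0.000789
```

The synthetic 1x-vs-5x experiment (4 replicate fields per condition, true
fold 2.3) is recovered by the full imaging chain within 6%, significant
at the one-sided α = 0.05.

`analysis/01_slope_theory.py` tabulates the model's K_D → slope curve and
its two limits.

## Library and CLI

The computation lives in `src/splitfp/`:

| module | contents |
| --- | --- |
| `splitfp.model` | `complemented_concentration`, `predicted_slope`, tandem-array pool model, `amplification_fold` |
| `splitfp.flow` | gating (`filter_saturated`, `scatter_gate`, `singlet_gate`), `log_transform`, thresholds, control-rescaled slope fits, `run_flow_analysis` |
| `splitfp.imaging` | `subtract_background` (rolling ball), `bandpass_mask`, `analyze_particles` (area/circularity filters), replicate histograms, `welch_one_sided`, `run_image_analysis` |
| `splitfp.simulate` | cytometry and microscopy generators with retained ground truth |
| `splitfp.io` | CSV and FCS 3.0/3.1 event-table ingestion, TIFF fields |
| `splitfp.config`, `splitfp.cli` | YAML project config and the `splitfp` command |

The CLI chains everything from one config:

```bash
splitfp slope-theory --kd-min 1e-3 --kd-max 1e7
splitfp end-to-end --config config.yaml --out run/
```

`end-to-end` simulates cytometry samples and imaging fields, analyzes
both, and writes JSON reports, plots and a `MANIFEST.json` with content
hashes; identical config + seed reproduces the reports byte for byte.

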