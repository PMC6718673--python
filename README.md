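# twinsig

Statistical tooling for iPSC-derived neuron studies of monozygotic twin pairs
discordant for schizophrenia. The package implements two analysis arms that
such studies need but that are usually buried in one-off scripts:

1. **Calcium-imaging twin contrasts** — turning per-ROI fluorescence time
   series into calibrated per-cell stimulus responses, and testing whether the
   affected twin (ST) differs from the unaffected co-twin (HT) across pairs
   with a two-level random-effects model.
2. **Sex-specific DEG overlap** — quantifying how much of an illness-related
   differential-expression signature falls inside the set of genes that
   already differ between healthy males and females, with Fisher exact and
   Pearson χ² tests and Venn partitions.

Because raw recordings from twin cohorts are rarely public, a synthetic-data
module generates both trace-level calcium cohorts and DEG tables with known
ground truth, so the whole pipeline is testable end to end.

## The model

**Response quantification.** Each cell trace has the background signal (mean
of the cell-free background ROIs) subtracted, then is denoised with a level-3
stationary (maximal-overlap) Haar wavelet transform: per level *j* the noise
scale is σ̂ⱼ = median(|dⱼ|)/0.6745 and the detail coefficients are
soft-thresholded at the universal threshold λⱼ = σ̂ⱼ√(2 ln N). The response to
each 2 s agonist application is

&nbsp;&nbsp;&nbsp;&nbsp;dF\* = (f − f₀) / f₀,

with *f* the maximum of the denoised trace in the 20 s window after onset and
*f₀* the minimum in the 50 s window before it. A cell counts as a neuron if
its KCl depolarization response is a sufficient fraction of its ionomycin
transient. Responses are calibrated by dividing by the ionomycin dF\* and,
for GABA and glutamate + glycine, additionally by the KCl response.

**Twin-contrast test.** Within each subject × treatment × stimulus stratum,
responses more than 3 × 1.4826 × MAD from the median are discarded; the
remaining cells give the subject mean and its variance s²/n. For each pair,
y = mean(ST) − mean(HT) with variance v = v_ST + v_HT. The pairs are pooled
with inverse-variance weights and a DerSimonian–Laird between-pair variance:

&nbsp;&nbsp;&nbsp;&nbsp;τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)),&nbsp;
w\*ᵢ = 1/(vᵢ + τ²),

giving the pooled ST−HT difference, its SE, Z = pooled/SE and a two-sided
normal p-value.

**Overlap enrichment.** A DEG list (adjusted p < 0.05 and |log2FC| ≥ 1) is
intersected with a reference set (e.g. sex-specific genes) inside a declared
universe; the 2×2 table yields Fisher exact and Pearson χ² p-values and an
odds ratio. Helpers convert log2 fold changes to linear folds (2^lfc) and
compute the signed GSEA ranking score log2FC × −log10(p_adj).

## Worked example

```python
import pandas as pd
import twinsig as ts

design = ts.CohortDesign(n_pairs=5, cells_per_subject=50,
                         true_pair_effect=0.3, between_pair_sd=0.1)
cohort = ts.simulate_twin_cohort(design, ts.TraceSimConfig(noise_sd=0.02), seed=1)
responses = pd.concat([ts.process_recording(r) for r in cohort.recordings],
                      ignore_index=True)
res = ts.twin_contrast_test(responses, "GABA", "pre")
res_post = ts.twin_contrast_test(responses, "GABA", "post")

print(f"pooled ST-HT difference: {res.pooled.pooled:.3f} (SE {res.pooled.se:.3f})")
print(f"tau^2 = {res.pooled.tau2:.4f}, Q = {res.pooled.Q:.2f}, k = {res.pooled.k}")
print(f"Z = {res.pooled.z:.2f}, p = {res.pooled.p:.2e}")
print("per-pair differences:",
      ", ".join(f"{p.pair_id}: {p.y:+.3f}" for p in res.pairs))
print("true pair effects:   ",
      ", ".join(f"{k}: {v:+.3f}" for k, v in cohort.pair_effects.items()))
print(f"post-treatment: pooled = {res_post.pooled.pooled:.3f}, p = {res_post.pooled.p:.2f}")
```

This simulates five discordant pairs whose affected twins' calibrated GABA
responses are shifted by pair effects drawn around δ = 0.3, pushes the traces
through the full pipeline (background subtraction, denoising, dF\*,
calibration, outlier filtering, two-level pooling), and prints:

```
pooled ST-HT difference: 0.269 (SE 0.058)
tau^2 = 0.0156, Q = 55.14, k = 5
Z = 4.64, p = 3.54e-06
per-pair differences: pair01: +0.241, pair02: +0.300, pair03: +0.229, pair04: +0.463, pair05: +0.110
true pair effects:    pair01: +0.236, pair02: +0.339, pair03: +0.261, pair04: +0.410, pair05: +0.033
post-treatment: pooled = 0.008, p = 0.56
```

The per-pair differences track the generating pair effects to within the
cell-level Monte-Carlo noise, the pooled estimate recovers δ, and the
post-treatment stratum — where the simulated effect is absent — is null.

The same flow is available from the shell:

```bash
twinsig simulate --out sim/ --seed 1 --pairs 5 --cells 50 --delta 0.3
twinsig traces --in sim/pair01_ST_pre.csv --events sim/pair01_ST_pre.json --out responses.tsv
twinsig test --responses responses.tsv --agent GABA --treatment pre --out result.json
twinsig overlap --degs degs.tsv --reference sex_specific.txt --universe universe.txt --out enrichment.json
twinsig run --out run/            # full end-to-end with a manifest
twinsig config --dump             # all defaults as YAML
```

## Layout

- `src/twinsig/synthetic_data.py` — trace, cohort and DEG generators
- `src/twinsig/trace_processing.py` — background subtraction, SWT denoising, dF\*, calibration
- `src/twinsig/response_stats.py` — MAD filter, subject summaries, DerSimonian–Laird pooling
- `src/twinsig/deg_overlap.py` — DEG filtering, overlap enrichment, Venn counts
- `src/twinsig/workflow.py`, `cli.py` — file formats, run config, orchestration, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
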