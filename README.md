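# saliotime

Reconstruct subjective duration judgements from salient events in
hierarchical perceptual time series.

## The scientific problem

People systematically misjudge how long things last: busy, eventful
intervals feel longer than quiet ones of the same clock duration. One
mechanistic account says the brain builds its sense of duration by
*accumulating salient events* — moments when activity patterns in a
perceptual processing hierarchy change more than a slowly relaxing
criterion expects. `saliotime` implements that account end to end:

1. summarize TR-to-TR pattern change per hierarchy layer (L1 or signed),
   z-scored within participant and layer;
2. detect salient events with a noisy, exponentially decaying criterion
   that resets after each event, with an artifact gate for extreme
   samples;
3. regress accumulated event counts onto presented duration
   (cross-validated support-vector regression, or in-sample OLS);
4. convert both human reports and model predictions to *normalized
   bias* — (x − cell mean) / cell mean — which removes clock time and
   leaves only the subjective distortion;
5. test whether the model's bias tracks the human bias: bootstrap slope
   tests, linear mixed models with AIC comparison, scene contrasts, and
   Bayes factors with prior-robustness regions;
6. map where in criterion-parameter space the association holds, via a
   grid robustness scan.

A synthetic generator (balanced designs, human-like reports, layered
activity driven by latent Poisson events convolved with a hemodynamic
response) makes every stage runnable and testable offline; ROI
extraction from 4-D NIfTI images connects the same pipeline to real
fMRI data. See `docs/methods.md` for the model, parameter defaults and
known limitations.

## Worked example

Simulate a small study — 6 participants, 20 trials each, a
scene-sensitive "visual" hierarchy (city scenes busier than office)
plus two scene-indifferent control hierarchies — then run the
confirmatory analysis:

```python
from saliotime import DesignSpec, confirmatory_config, run_pipeline, simulate_dataset

trials, series, latent = simulate_dataset(
    design=DesignSpec(n_participants=6, blocks_per_participant=1,
                      trials_per_block=20, seed=0),
    seed=0,
)
print("trials:", trials.shape, "| series:", len(series))
print(trials.head(3).round(2).to_string(index=False))

report = run_pipeline(confirmatory_config(seed=0, n_boot=2000), trials, series)

vis = report.hierarchies["visual"]
print(f"visual pooled mapping r = {vis.r_pooled:.3f}")
boot = vis.results["bootstrap_slope"]
print(f"bootstrap slope test: beta = {boot.estimate:.3f}, "
      f"one-tailed p = {boot.p:.4f} (B = 2000)")
scene = vis.results["scene_contrast_model"]
print(f"model-bias scene contrast: t = {scene.stat:.3f}, p = {scene.p:.4f}")
print(report.comparison.round(3).to_string(index=False))
```

Output:

```text
trials: (120, 6) | series: 1080
 participant  block  trial  scene  duration_s  report_s
           0      0      0 office        12.0     11.42
           0      0      1   city        24.0     24.81
           0      0      2   city        12.0     13.76
visual pooled mapping r = 0.708
bootstrap slope test: beta = 0.126, one-tailed p = 0.0905 (B = 2000)
model-bias scene contrast: t = 8.096, p = 0.0000
        model    llf  llr_vs_reduced      aic  delta_aic  best
       visual 67.889           2.024 -131.779      0.000  True
     auditory 66.939           0.124 -129.879      1.900 False
somatosensory 66.881           0.008 -129.763      2.016 False
```

Even at this small scale the pipeline behaves as the model predicts:
event counts track duration (pooled r = 0.708), the model's bias is
strongly scene-dependent (t = 8.10) because the city scene generates
more latent events, and the visual hierarchy explains human bias better
than both controls by AIC. The human-model slope itself is positive but
not significant at n = 120 trials — the association test needs
full-study sample sizes (see the dissociation and scan tests in
`tests/test_acceptance.py`, which use larger designs and report
coupling).

The same steps are available as a CLI:

```bash
saliotime simulate --seed 0 --out data/
saliotime run --data data/ --preset confirmatory --seed 0 --out results/run/
saliotime scan --data data/ --hierarchy visual --out results/scan/
saliotime stats --analysis bf --mean 5.23 --se 1.69 --prior half_normal --prior-scale 10.5
```

## Reproduction

All randomness is seed-controlled; rerunning any command or function
with the same seed reproduces its output byte for byte (the test suite
asserts this for the generator, the detector, the scan and the full
pipeline summary JSON).

To recompute the summary acceptance targets from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This writes a JSON object with one entry per target: the normalized
bias of probe trials reporting 0.5x, 1.0x and 1.5x their duration-cell
mean (−0.5, 0.0 and +0.5 for any seed, since the statistic depends only
on the ratio), and the Bayes factor for a scene contrast of mean 5.23,
SE 1.69 under a half-normal(0, 10.5) prior (33.8 to one decimal). The
full test suite, including the Monte-Carlo acceptance tests, runs with
`python -m pytest -q tests/`.
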