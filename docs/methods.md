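# Methods note

## Model

`saliotime` implements an accumulator model of subjective duration: the
feeling of elapsed time in a trial is read out from the number of
*salient events* — abrupt changes — detected in hierarchical perceptual
time series (ROI-wise BOLD sampled every TR, or layered network
activations). The pipeline has five stages:

1. **Change.** For each trial, hierarchy layer and TR, the activity
   pattern's movement from the previous TR is summarized either as the
   L1 change `delta_TR = sum_v |X[TR,v] - X[TR-1,v]|` (confirmatory
   metric) or the signed change `delta'_TR = sum_v (X[TR,v] - X[TR-1,v])`
   (exploratory metric). Changes are never computed across trial
   boundaries; the first TR of a trial carries no value. Change values
   are z-scored pooling all of a participant's valid TRs within a layer
   (sample SD, ddof 1), so thresholds are in SD units.
2. **Salient-event detection.** A standardized change is salient when it
   meets a noisy criterion that decays exponentially from a conservative
   starting point toward a floor: `theta(k) = theta_min + (theta_max -
   theta_min) * exp(-k/tau) + eps`, `eps ~ N(0, noise_sd^2)`, where `k`
   counts TRs since the last reset (k = 1 at the first comparison). The
   criterion resets to its maximum after each salient event and at trial
   end. Values beyond an artifact cutoff (default 2.5 SD; two-sided for
   the signed metric, one-sided for L1) are excluded and, by default,
   freeze the decay clock. Default layer criteria (theta_max = 1.0, 1.5,
   2.0 SD for layers 0-2) are configuration, not empirical claims.
3. **Accumulation and mapping.** Salient events are counted per trial
   and layer, and the per-layer counts are regressed onto the *presented*
   (never the reported) duration — epsilon-SVR with k-fold
   cross-validation for the imaging path (out-of-fold predictions only;
   feature scaling fitted on training folds), or in-sample multiple
   linear regression for the classification-network path.
4. **Normalized bias.** For trial k of duration category t, `bias_tk =
   (x_tk - mean_t) / mean_t`. Its cell mean is exactly zero, and it is
   independent of clock time, isolating the subjective component of
   reports and predictions alike. Human bias is computed either per
   participant x duration cell or on a pooled "super-subject".
5. **Inference.** Scene contrasts (paired or two-sample t), the
   bootstrap slope test of human on model bias (one-tailed permutation
   p with +1 correction), random-intercept linear mixed models compared
   by likelihood-ratio chi-squared tests and AIC (maximum likelihood,
   not REML, so log-likelihoods are comparable), and Bayes factors with
   half-normal or uniform directional priors, normal likelihood, and a
   log-grid robustness region. A robustness scan re-runs stages 2-5 over
   a grid of criterion bounds and maps where the human-model association
   holds.

## Super-subject pooling

Reports are z-scored within participant (removing idiosyncratic scale
and offset) and re-anchored onto the grand mean and SD of all reports,
so the pooled series lives on a positive seconds scale and normalized
bias stays well defined. With a single participant this round-trips the
original reports exactly. Limitation: with extreme between-participant
scale ratios (roughly > 5x) a low z-score can re-anchor to a
non-positive pooled report, which the bias computation rejects loudly.

## Synthetic generator

The generator emulates the structure the analysis assumes, so every
stage runs without downloads: balanced designs (durations 8-24 s x
scenes office/city, TR 0.8 s), human-like reports (affine
regression-to-the-mean map with multiplicative noise, lognormal
participant gain, a city-scene factor `1 + pct/100`, truncated to the
0-40 s response scale), and layered activity driven by latent Poisson
events. Each event deposits amplitude on a random channel subset; the
impulse train is convolved with a canonical double-gamma hemodynamic
response (peak 6 s, undershoot 16 s — the forward model is a
documented choice, any smooth kernel would serve), then random-walk
drift, white noise and optional global artifact spikes are added.
Latent event times are returned for recovery tests.

With the city-only scene factor, the noise-free normalized-bias scene
difference is `(s/100) / (1 + s/200)` — about 4.88% at the default
`scene_bias_pct = 5` — which the tests assert in closed form.

## Numerical choices

- z-scoring uses sample SD (ddof 1).
- Bootstrap p-values use the +1 correction and are never exactly zero.
- Mixed models are fitted by ML with an optimizer ladder (BFGS, L-BFGS,
  CG, Powell); a random-intercept variance pinned at zero is accepted as
  a boundary ("singular") fit rather than an error.
- Bayes-factor integrals substitute `theta = scale * u` so adaptive
  quadrature stays accurate for prior scales far narrower than the
  likelihood; agreement with 10^6-point trapezoid integration to 4
  significant figures is asserted in the tests.
- Grid-scan cells use the analytic one-tailed OLS slope test (a
  bootstrap per cell would buy nothing) and derive their RNG streams
  from (seed, i, j), making cells order-independent.

## Study-scale choices in the test suite

Monte-Carlo suites run at desk scale; the sizes are package choices,
fixed before the assertions were frozen:

- Dissociation: 8 participants x 20 trials, reports generated from the
  visual hierarchy's latent events (rates office 0.25 / city 0.5
  events/s/layer; two scene-flat control hierarchies at 0.35), 50
  seeds.
- LMM recovery: 40 participants x 60 trials, true slope 0.5, 100 seeds.
- Bootstrap calibration: 400 null runs at B = 1000.
- Robustness scan: 10 x 10 grid, 40 participants x 20 trials, averaged
  over 6 dataset seeds; visual rates office 0.4 / city 0.5, control
  flat at 0.45; reports from visual latent counts with CV-0.15 noise.

## Known limitations

- **Deep-floor saturation.** When the criterion floor sits below
  essentially all standardized changes (theta_min below about -2 SD at
  low theta_max), every compared TR crosses within one or two steps,
  counts saturate at the number of TRs, and the accumulator carries
  clock time only — no subjective-bias information survives, regardless
  of coupling strength or sample size. In the robustness scan these
  cells are genuinely dark; they bound the attainable significant-cell
  fraction among theta_max > 0.5 cells near 0.65 under strong coupling
  at the 40-participant scale.
- **Shared-draw variance in the scan.** All cells of one scan reuse one
  dataset, so the per-dataset fraction of significant cells in a pure
  noise hierarchy is nearly binary across dataset draws (usually ~0,
  occasionally large when the control's detected-count bias
  chance-aligns with human bias). The scan acceptance test therefore
  averages over six datasets rather than trusting one.
- **Per-trial recovery floor.** Under the HRF forward model, events
  falling within the response rise-time of trial end are unobservable
  and near-coincident events merge, so per-trial relative count error
  has a floor around 0.35 even at low noise. Recovery is therefore
  asserted as rank agreement (Spearman rho > 0.8) plus mean-count
  calibration within 20%, not per-trial equality.
- Detection thresholds are not learned from data; no HRF deconvolution
  is applied before detection; fMRI preprocessing is out of scope (ROI
  masks and 4-D images are accepted as input).
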