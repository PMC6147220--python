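# samloc — double-sound localization in elevation

`samloc` is a tested, reusable pipeline for studying how human listeners
localize two *synchronous* broadband sounds in the midsagittal plane, where
only pinna-induced spectral-shape cues carry elevation information. One
sound (the target) is a sinusoidally amplitude-modulated Gaussian white
noise (AM, modulation frequency 5, 120 or 2000 Hz); the other (the
distractor) is a flat band-limited noise (GWN, 0.5–20 kHz). The central
empirical question is whether temporal envelope cues let the auditory
system segregate the two sources — or whether the perceived location is a
compulsory **level-weighted average** of the two source locations.

The package covers the full computational analysis:

- **`samloc.stimuli`** — stimulus synthesis (band-limited GWN, 100 % AM
  noise with the envelope `e(t) = 1 − depth·cos(2π·fm·t + φ)`, sin²/cos²
  ramps, relative-dB level handling) and time-windowed power analysis of
  the phase-dependent *initial* level difference between AM and flat noise.
- **`samloc.design`** — the three factorial trial tables: localization
  (720 double + 119 single = 839 trials; ΔL ∈ {−10, −5, 0, +5, +10} dB),
  frequency discrimination (120 + 60) and phase discrimination (480),
  with seeded pseudo-random interleaving and lossless CSV round-trips.
- **`samloc.simulate`** — synthetic behavioral data: localization endpoints
  under the weighted-average model, a bistable rival model, binomial 2AFC
  choices, and smooth head-orientation traces with single minimum-jerk
  saccades.
- **`samloc.preprocess`** — head-saccade detection (10 °/s velocity
  threshold), reaction-time and profile QC (150 ms cut, single-peak rule),
  head-still checks for discrimination trials.
- **`samloc.infer`** — Bayesian inference by adaptive Metropolis-within-Gibbs
  MCMC, 95 % highest-density intervals, Gelman-Rubin convergence
  diagnostics, and Savage-Dickey Bayes factors.
- **`samloc.report`** — weight-vs-ΔL and variability summary tables,
  identification-rate tables, and a reproducible end-to-end pipeline driver.

## The models

Single-sound responses follow a linear stimulus–response law with gain *g*
and bias *b*:

    R_s ~ Normal(g·T + b, σ_s)

Double-sound responses follow the weighted-average (WA) model, where the
target weight *w* ∈ [0, 1] measures the target's relative contribution
(per level-difference × modulation-frequency condition):

    R_d ~ Normal(g·(w·T + (1−w)·D) + b, σ_d)

*w* = 0 means the response tracks the distractor, 1 the target, and 0.5 pure
averaging; with *w* = 1 the WA model reduces exactly to the single-sound
law. Priors: b ~ N(0°, 10°), g ~ N(1, 10), σ ~ Gamma (flat over plausible
values), w ~ Beta(1, 1). The joint model shares (g, b, σ_s) across all
interleaved trials of a listener and fits (w, σ_d) per condition with
3 MCMC chains × 10 000 samples (5 000 burn-in), requiring R-hat < 1.1.

2AFC identification uses K ~ Binomial(θ, N) with a uniform prior, so the
posterior is Beta(K+1, N−K+1) exactly; the Savage-Dickey Bayes factor
against H0: θ = 0.5 is the prior/posterior density ratio at 0.5, labelled
substantial / strong / very strong / decisive at 3 / 10 / 30 / 100.

## Worked example

```python
from samloc import design, simulate, infer, report

trials = design.build_localization_trials(seed=7)        # 839 trials
params = simulate.paper_like_params()                    # w ≈ 0 → 1 over ΔL
responses = simulate.simulate_localization(trials, params, seed=3)

singles, doubles = infer.join_responses(trials, responses)
post = infer.fit_localization(singles, doubles, n_chains=3,
                              n_samples=10000, n_burn=5000, seed=11)
print(f"max R-hat: {post.max_rhat():.3f}")
curves = report.weight_curves(post)
print(curves[curves.fm_hz == 120.0].round(3).to_string(index=False))
```

prints

```
max R-hat: 1.003
 delta_l_db  fm_hz  w_mean  w_sd  w_hdi_lo  w_hdi_hi  sigma_d_mean  sigma_d_sd
      -10.0  120.0   0.045 0.027     0.000     0.094         9.343       1.008
       -5.0  120.0   0.047 0.033     0.000     0.109        12.996       1.344
        0.0  120.0   0.525 0.055     0.414     0.628        15.652       1.618
        5.0  120.0   0.904 0.036     0.833     0.973        10.033       1.097
       10.0  120.0   0.971 0.022     0.928     1.000        10.237       1.076
```

All chains converged (R-hat ≤ 1.003). The recovered target weights rise
monotonically from ≈ 0 at ΔL = −10 dB (distractor 10 dB louder: responses
ignore the target) through ≈ 0.5 at equal level (pure averaging) to ≈ 1 at
+10 dB, and the double-sound response SD peaks at the averaging point —
the signature level-weighted-average pattern the generator encodes.

For discrimination data:

```python
res = infer.fit_discrimination(k=30, n=160)
print(f"theta = {res.theta_mean:.3f}, 95% HDI = ({res.hdi_95[0]:.3f}, "
      f"{res.hdi_95[1]:.3f}), BF10 = {res.bf10:.3g} ({res.evidence})")
# theta = 0.191, 95% HDI = (0.132, 0.252), BF10 = 3.3e+13 (decisive)
```

Here identification is far *below* chance — the listener systematically
points at the distractor — and the Bayes factor is decisive against
θ = 0.5.

A command-line interface mirrors the library (`samloc stimgen`, `samloc
design`, `samloc simulate`, `samloc detect`, `samloc fit`, `samloc report`,
`samloc pipeline`); see `samloc --help`.

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline's headline computation from
scratch: it builds a full localization session, simulates one listener
under the weighted-average model, fits the joint Bayesian model with
3 chains × 10 000 samples (5 000 burn-in), and reports the maximum
Gelman-Rubin diagnostic across all 33 parameters:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes well under a minute on one CPU.
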