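# Methods

This note documents the scientific and numerical choices behind `samloc`:
what each stage models, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Stimuli

Carriers are Gaussian white noise band-limited to 0.5–20 kHz at the
hardware sample rate 48 828.125 Hz, filtered with a 1025-tap zero-phase FIR
(forward–backward application), giving > 40 dB out-of-band rejection
without skewing the temporal envelope. Each carrier is deterministic in its
integer seed; the AM and GWN carriers of one trial derive *distinct* child
seeds so the two noises are uncorrelated.

**Envelope convention.** Amplitude modulation multiplies the carrier by

    e(t) = 1 − depth · cos(2π·fm·t + φ),

so at φ = 0 the envelope *starts at its minimum* (zero, at 100 % depth).
This convention is deliberate and load-bearing: a 5 Hz AM sound at phase 0
is initially softer than a level-matched flat noise, which is the proposed
mechanism for the observed bias toward the unmodulated distractor at low
modulation frequencies and for the rightward (+3 dB) shift of the 5 Hz
weight curve. After modulation the waveform is renormalized to the
carrier's RMS over the **full duration**, mirroring the physical
per-stimulus level calibration. For stimuli spanning ≥ 2 full modulation
periods this preserves RMS regardless of phase; for 5 Hz at 150 ms (0.75
period) a phase-dependent residual remains and is deliberately retained,
because the physical stimuli had the same property.

Onset/offset ramps are sin²/cos², default 5 ms (the source text omits the
number; 5 ms is a conventional click-suppression ramp and is configurable).
Levels are relative dB re a software reference RMS (55 dB ↔ RMS 0.1);
A-weighting and absolute SPL belong to the presentation hardware and are
out of scope.

**Initial-power analysis.** `windowed_power_difference` returns
10·log₁₀(P_AM/P_GWN) over the first *w* ms of two full-duration-equalized
sounds. `phase_power_profile` sweeps the modulation phase, comparing each
modulated sound against its own unmodulated carrier (this isolates the
envelope's contribution; with depth 0 the difference is exactly 0 dB,
whereas an independent distractor noise would add ≈ 0.4 dB of seed scatter
to each sample without changing the mean). For a finite window the
profile's extrema sit at the phases where the *windowed envelope-energy
integral* is extreme — for a 50 ms window on 5 Hz AM that is a quarter of a
modulation-period before phase 0/π (i.e. at 7π/4 and 3π/4), not at 0/π
exactly; the tests check against the windowed-integral oracle, not the
naive instantaneous-minimum heuristic.

## Trial designs

The experiments' printed factorials are reproduced exactly. The 24
double-sound elevation pairs are not enumerated in the source, so the
package freezes a versioned configuration (`data/double_sound_pairs.csv`):
pairs on the 5° cardinal-axis grid within [−45°, +75°], separations tiling
{15, 30, 45, 60, 75}° with counts {5, 5, 5, 5, 4}, constructed so exactly
17 unique elevations occur — making 7 sound kinds × 17 locations = 119
single-sound trials and 839 trials in total. Per double trial the AM level
is drawn uniformly from the calibrated set {45…65 dBA} subject to both
sounds staying in range at the required ΔL.

Two count ambiguities were resolved as package decisions: the 60
frequency-discrimination singles are balanced over modulation frequency
(2 positions × 3 fm × 10), and the phase experiment's "2 sound types"
factor is read as the modulated target being either the pure 5 Hz AM noise
or the superimposed GWN+AM composite (both kinds exist as singles in the
localization design). Session splitting is metadata only.

## Synthetic behavior

The generator emulates the *stated world* of the task, not a process model
of how weights arise from acoustics:

- localization endpoints are Normal around the weighted-average prediction
  (singles: `g·T + b` with σ_s);
- `paper_like_params()` encodes the qualitative group-level findings as the
  generating truth: w(ΔL) logistic with slope 2.5 dB, equal-weight point at
  0 dB for 120/2000 Hz and +3 dB for 5 Hz; g = 0.85 and σ_s = 9° (inside
  the observed single-sound ranges 0.82–0.90 and 8.2–10.9°); σ_d =
  10 + 20·w(1−w) deg, peaking at the averaging point;
- the bistable rival draws each endpoint around target or distractor
  (probability `p_target`) with single-sound accuracy — its mean matches a
  WA fit but its residual spread around the WA prediction is strictly
  larger, which is the fitted-σ_d signature used to contrast the models.
  The rival's parametrization is this package's construction; no
  quantitative bistable model exists in the source;
- 2AFC choices are Bernoulli with per-condition rate θ;
- head traces (6 kHz, 1500 ms) hold fixation, execute one minimum-jerk
  saccade (duration 120 ms + 1.5 ms/deg) after a truncated-Normal(250, 50)
  reaction time bounded at 160 ms (so default data pass the 150 ms QC cut),
  and carry white sensor noise shaped by the 120 Hz acquisition anti-alias
  filter.

Not emulated: free-field acoustics and HRTF filtering, eye movements,
azimuth responses (fixed 0° + noise), attention lapses, or any
trial-history effects. A green recovery test therefore establishes that
the *inference machinery* is calibrated for data of the assumed form — not
that real listeners satisfy the model.

## Saccade detection

Velocity is the Euclidean norm of the azimuth/elevation derivatives after
zero-phase 4th-order Butterworth smoothing at 40 Hz (between the saccade
band and the 6 kHz noise floor). Onset/offset are the first upward and the
next downward crossing of the 10 °/s threshold; the first/last 25 ms of a
trace are excluded from the search because forward–backward filtering
leaves edge transients there. The endpoint estimator — undefined in the
source — is the mean orientation over 100 ms starting 50 ms after offset.
"Anomalous profile" is operationalized as more than one velocity peak above
threshold (prominence ≥ half the threshold) between onset and offset or a
re-acceleration after offset; the original manual inspection cannot be
reproduced. QC discards null responses, anomalous profiles and reaction
times < 150 ms (exactly 150 ms is kept). The end-to-end round trip recovers
endpoints within 1° and RTs within 20 ms over the full ±45–75° range at
default noise.

## Inference

The joint localization model shares (g, b, σ_s) across all interleaved
trials of a listener and gives each (ΔL, fm) condition its own (w, σ_d) —
honoring both the per-condition fits and the statement that gain and bias
are common to single and double trials. A strict per-condition ablation can
be run by fitting subsets. Priors: b ~ N(0°, 10°), g ~ N(1, 10),
w ~ Beta(1, 1), σ ~ Gamma(shape 1, rate 0.04) — the Gamma hyperparameters
are not printed in the source; this choice has mean 25° and is essentially
flat over 0–50°, and a mandatory sensitivity test verifies that halving or
doubling (shape, rate) moves weight posterior means by < 0.02 at
experiment-scale n.

The sampler is adaptive random-walk Metropolis-within-Gibbs: scalar updates
for g, b and log σ_s, and *blocked* vector updates for {w_c} and
{log σ_d,c} (conditions are conditionally independent given the shared
parameters, so proposals are accepted/rejected per condition in one
vectorized step). Weight proposals reflect at the [0, 1] boundaries (step
capped at 0.5 so a single reflection suffices); SD proposals walk in log
space with the Jacobian term. Step sizes adapt toward ≈ 38 % acceptance
every 50 iterations *during burn-in only*, leaving the kept chain a valid
Markov chain. Chains start from prior draws (SDs clipped to ≥ 0.5° to
avoid numerically absurd starts). Defaults follow the analysis protocol —
3 chains × 10 000 samples, 5 000 burn-in — and a full 839-trial fit takes
≈ 5 s on one CPU with max R-hat ≈ 1.005.

Diagnostics and summaries: R-hat is the classic Gelman-Rubin PSRF with the
Brooks-Gelman (m+1)/m correction (identical chains give 1 up to the
(n−1)/n finite-sample factor); HDIs are the shortest contiguous interval
over sorted samples; Savage-Dickey BF₁₀ is the prior/posterior density
ratio at the null, computed analytically in the conjugate Beta case and by
Gaussian KDE (Silverman bandwidth) otherwise, the KDE path being validated
against the analytic case. The discrimination posterior Beta(K+1, N−K+1) is
exact; an independent brute-force marginal-likelihood oracle
(log-space adaptive quadrature) agrees with the analytic BF to < 1e−9
relative, and an RWM sampler cross-checks conjugacy and prior recovery.

Pooling across subjects concatenates posterior samples (the protocol pools
samples, not parameters — no hierarchical shrinkage); group means and HDIs
are computed on the pooled draws.

**Calibration.** The recovery test uses one experiment-scale condition
(48 doubles from the frozen 24 pairs + 17 singles, truth w = 0.5, g = 1,
b = 0, σ_s = 8°, σ_d = 10°) and checks, over 200 independent replicates,
that the posterior-mean bias of w stays below 0.05 and that 95 % HDIs cover
the truth in 93–97 % of replicates. 200 replicates (rather than 50) are
used because the sampling SD of a coverage proportion at n = 50 (≈ 3.1 %)
is wider than the 93–97 % acceptance band itself; even at n = 200 the band
is statistically snug (≈ 80 % pass probability under perfect calibration),
which is accepted as-is rather than widening the band.

## Known limitations

- The sampler is random-walk based; for much larger designs HMC would mix
  better per iteration, but at this problem size (33 parameters, 839
  observations) convergence is comfortably inside the protocol's budget.
- Bistable data are fit with the WA likelihood only (inflated σ_d is the
  detection signature); no explicit mixture model is estimated.
- The phase-experiment θ(φ) link to the initial-power profile is left
  qualitative in the generator defaults; the package provides the pieces
  (profile + per-phase discrimination fits) but does not posit a
  quantitative psychometric mapping.
- WAV files are written at the rounded integer rate 48 828 Hz (WAV headers
  cannot carry the exact 48 828.125 Hz, which is recorded in the sidecar
  JSON).
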