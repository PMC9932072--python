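# Methods

This note documents the models, estimators and numerical choices behind
`hexkin`, what the synthetic generator does and does not emulate, and the
known limitations of the published analysis conventions the package
implements.

## Camera model

EMCCD output for a pixel receiving a Poisson number of photons (mean `E`)
through a stochastic electron-multiplying register is modeled as
`s = s0 + Gamma(shape = N, rate = γ)` with `N ~ Poisson(E)`; shape-0 draws
collapse to the offset `s0` exactly.  The marginal density is the
Poisson⊛Erlang mixture with a δ-spike of mass `e^−E` at `s0`.  The
continuous part is evaluated on the offset-corrected argument `x = s − s0`:
only this convention satisfies the zero-photon limit and the mean identity
`⟨s⟩ = s0 + E/γ`, both verified by quadrature in the test suite.

**Fitting.**  Each selected pixel's integer-count histogram is fit by
minimum-χ² (Nelder–Mead on moment-based initial values, parameters scaled
to unity).  Bin probabilities come from the mixture CDF
`e^−E·1[x ≥ 0] + Σ_k Pois(k; E)·GammaCDF(x; k, γ)` so the δ-spike is an
ordinary bin, never a narrow-Gaussian approximation.  Integer bins are
merged until the expected count per bin is at least 5 (capped at ~80 bins
to bound cost); the goodness p-value uses `bins − 3 − 1` degrees of
freedom.  Calibration selects 400 random pixels without replacement,
averages `s0` and `γ` over fits with p > 1 %, and refuses to proceed with
fewer than 10 accepted fits.  On synthetic 4000-frame stacks the averaged
offset is recovered within ~0.5 % and the inverse gain within ~0.5 %;
the residual offset bias (~half a count) comes from integer rounding of
the output counts.

## Illumination correction

The profile estimate is the movie's time average convolved with a wide
Gaussian (σ = 30 px, reflective boundaries).  Division by the raw profile
would destroy photon units, so the correction rescales by the profile
maximum: pixel values stay in photons referenced to the illumination peak,
and equally bright particles anywhere in the field read the same.  Two
caveats are inherent to the estimator and demonstrated in the tests:
(a) the reflective boundary flattens the estimate within ~2 kernel widths
of the edge, so fields must be large compared to 60 px for accurate
correction near corners; (b) the particles' own light leaks into the
profile estimate, biasing extracted intensities down by roughly the
spot-light fraction of the background (a few percent at typical particle
densities).  A temporal Gaussian smoothing (σ = 3 frames) is applied only
to the detection copy of the movie; photometry always uses unsmoothed
frames, because temporal smoothing at a 0.15 s frame interval would
distort dwell kinetics.

## Localization and photometry

Detection runs on the time average (particles are immobile): a band-pass
(short-scale Gaussian minus boxcar), local maxima with a 6 px minimum
separation, and an integrated-mass threshold of 0.4 × the mean of the
averaged movie.  Survivors are refined by least-squares 2-D Gaussian fits
(x, y, amplitude, σx, σy, baseline).  Fits with axial ratio outside
[1, 1.6] are rejected as merged or distorted spots.  Coordinates are
0-based with pixel centers at integers, origin top-left.

Photometry integrates the discrete circular ROI of diameter 9 px
(69 pixels) centered on the rounded centroid and subtracts
`baseline × 69`, the baseline being the per-particle Gaussian-fit value
from the time average, reused for all frames.  For a σ = 1.5 px spot the
ROI captures 98.9 % of the light.  End to end (camera calibration →
photon conversion → illumination correction → photometry), synthetic
monomers emitting 46 photons/frame are recovered within 5 %.

Quality control: traces with any frame above 500 photons are discarded as
higher-order aggregates.  Monomeric-control traces are additionally
scanned for bleaching (400-frame block mean ≤ 30 photons) and blinking
(frames 100–1000 whose deviation from the trace mean reaches 3 trace
standard deviations; the absolute-deviation count and the negative-only
dark-state count are both reported, since the sign convention is a choice).

## Trace idealization

Seven Gaussian emission states: background (20 ± 25), monomer (50 ± 25),
then 100/150/200/250/300 all ± 35 photons.  Emission parameters are frozen
— the higher oligomers are too rare for stable re-estimation — and only
the transition matrix and initial distribution are learned per trace by EM
(uniform start, ≤ 500 iterations, tolerance 10⁻⁶).  States the trace never
visits leave empty transition rows; these are repaired to inert
self-transitions before Viterbi decoding.  Decoding uses Viterbi rather
than posterior argmax because dwell analysis needs one self-consistent
path.  No minimum dwell is imposed.

On noisy synthetic traces with the frozen level spacing, σ = 14 emission
noise and dwells of ≥ 5 frames, frame-level accuracy exceeds 95 % and
pooled residuals form a zero-centered Gaussian of width ≈ 14 photons.
Misassigned frames near state boundaries put a few percent of residuals in
heavy tails, so formal normality tests only pass on ensembles whose states
are well separated relative to the noise.

## Dwell-time kinetics

Transitions touching S0 are excluded from the 6×6 grid.  Each transition
record carries the dwell in the departing state; only interior dwells
(entry *and* exit observed) enter rate fits, while first segments count
toward densities only — this avoids entry-censoring bias while keeping the
density bookkeeping complete (cluster densities always sum exactly to the
number of enumerated transitions).  Dwells above 75 s are excluded by
simple truncation, with no truncated-likelihood correction, exactly as the
convention prescribes.  The exponential MLE is `rate = 1/mean(dwell)`;
errors come from a nonparametric bootstrap (1000 resamples) and, as a
variant, from per-video refits.

Two systematic effects matter and are characterized by the recovery
tests rather than corrected:

- **Window censoring.**  In a recording of length `T`, dwells comparable
  to `T` rarely complete, biasing the retained sample short and the rate
  up by roughly `mean dwell / T`.  At the acquisition's 4000 frames
  (600 s) and dwells of ~10–20 s this is a 2–3 % effect; it grows fast
  for shorter recordings.
- **Missed events.**  Viterbi absorbs dwells much shorter than ~6 frames
  at this signal-to-noise, merging their neighbors and biasing rates
  down.  With mean dwells ≥ 100 frames the loss is a few percent.  The
  parameter-recovery conditions (k·c and k around 0.05 s⁻¹, i.e. mean
  dwells ≈ 20 s ≈ 130 frames, 4000-frame traces) sit where both effects
  are small, and the pipeline then recovers planted association and
  dissociation constants within a few percent at ≥ 2000 events.

**Competing exits.**  Per-cluster single-exponential fitting is the
transition-density convention: each channel's dwell sample follows the
*total*-exit exponential, so with several exit channels the per-cluster
rate estimates the total exit rate, not the channel's own.  This is
implemented as published; `competing_risks_rates` provides the corrected
diagnostic (total rate × channel event fraction), whose per-state sum
reproduces the total exit rate.

**Solution composition.**  Assembly-step photon increments are fit with a
five-component Gaussian mixture whose means are frozen at `m·μ`
(m = 1..5, μ from the monomer calibration) with SDs `√m·σ` — independent
fluorophores add in variance — and free weights (EM; an emptied component
keeps weight 0).  Weights are number fractions of the free species.  The
conversion to molar concentrations is not uniquely determined by the
measurement; `hexkin` conserves monomer equivalents:
`c_m = w_m · C_N` with `C_N = C_mono-equiv / Σ m·w_m`.  Quantities
downstream of this convention (all bimolecular constants) inherit it.

**Occupancies** use the same mixture machinery with seven components at
the emission-table means; errors are SDs over ten parametric-bootstrap
refits.

## Thermodynamics and statistics

`R = 8.314 J mol⁻¹ K⁻¹`, `T = 298 K`, CODATA `k_B` and `h`.
`K_eq = k_ij/k_ji`, `ΔG = −RT ln K_eq`,
`ΔG‡ = −RT ln(h·k/(k_B·T))`.  Condition comparisons use Welch's
unequal-variance t-test from summary statistics (n = number of videos)
with the conventional star mapping; fold ratios carry first-order error
propagation and significant-figure rounding.

## Synthetic data

The generator emulates: exact continuous-time Markov state switching with
assembly propensities `k·c(added species)` under constant solution
concentrations (open system); exposure-weighted state averaging over the
50 ms exposure window only, the 100 ms dead time being unobserved —
reproducing missed-event behavior at the 6.7 s⁻¹ frame rate; emission
noise of width `σ_monomer·√state` (per-fluorophore noise adding in
variance; constant-σ selectable); pixel-integrated Gaussian PSFs; a
peak-normalized Gaussian illumination profile that modulates both particle
light and the excitation-driven background; and the exact generative
inverse of the camera model.  Simultaneous double-dimer additions are not
generated (step sizes 1, 2 and 4 only by default), and bleaching/blinking
gates are modeled at the whole-particle level, which is exact for the
single-fluorophore monomer controls they exist to emulate.

Not emulated: diffusing particles, 3-D/astigmatic PSFs, irreversible
aggregation, drift, clock-induced charge, and solution-concentration
depletion during an experiment.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise and
kinetic model, not robustness to these additional real-data effects.

## Mass-action model

Species S1..S6 couple through monomer additions `S_m + S1 ⇌ S_{m+1}`,
dimer self-association `S2 + S2 ⇌ S4`, and tetramer addition
`S2 + S4 ⇌ S6`.  The reverse of the last is implemented as two parallel
first-order channels (`k62`, `k64`) summing in the hexamer loss term, each
firing regenerating one dimer and one tetramer; `k64` defaults to the
0.01 s⁻¹ upper-bound convention.  Stoichiometric factors follow
`d[S2]/dt = +k12[S1]²`, `d[S1]/dt = −2k12[S1]² + 2k21[S2]` (and the same
factor 2 for S2 + S2 ⇌ S4), which makes `Σ m·[S_m]` exactly conserved;
the integrator (BDF, rtol 10⁻⁸, atol scaled to the initial concentration)
holds conservation to ~10⁻⁹ relative over 300 s.  The forward rate of
S2 + S4 → S6 uses `k26`; a switch substitutes `max(k26, k46)` when a
tetramer-side measurement exists.  Endpoint fractions are particle-number
normalized (`f_m = [S_m]/Σ[S_j]`; monomer-equivalent weighting
selectable), the mean oligomeric state is `Σ m·f_m`, and the default
concentration sweep is a log grid from 1 nM to 1 mM.

The Hill fit uses bounded nonlinear least squares on the hexamer fraction;
flat input returns a flagged failure rather than parameters.  Apparent
Hill coefficients below 1 arise when successive assembly steps have
heterogeneous affinities, stretching the hexamer onset over concentration
— the regime the representative test schemes (strong early, weaker late
steps) reproduce.

An exact Gillespie simulation of the same network (bimolecular propensity
`k·n_i·n_j/(N_A·V)`, `k·n(n−1)/(N_A·V)` for identical reactants) serves as
an independent cross-check of the deterministic integrator; at 10⁵
particles the dimerization toy agrees with the ODE within 1 %.

## Problem sizes

Defaults used by the test suite and the reproduction script, chosen to
sit where the estimators' asymptotics apply while remaining desk-scale:
camera calibration on 4000-frame 48×48 stacks (400 pixel fits);
photometry on a 200-frame 128×128 movie with 50 particles; idealization
accuracy on 200 traces of 400 frames; rate recovery on 170 traces of 4000
frames (~2200 events per transition); stochastic cross-check at 10⁵
particles.
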