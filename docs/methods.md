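# Methods

## The model

`shakeflask` models photoautotrophic growth of *Chlorella vulgaris* in
500 mL conical flasks illuminated from below by an LED tablet and agitated
on an orbital shaker. Because the lamp sits under the flask and the culture
is well mixed, the flask behaves optically like a flat panel reactor of
depth `h` (the liquid height): all cells at a given height receive the same
light, and every cell samples all heights uniformly over time.

**Light field.** The intensity actually entering the culture, `I0`, differs
from the lamp set-point `I_S`; the device calibration is a quadratic
regression

    I0 = c0 + c1 * I_S + c2 * I_S**2,

with defaults (6.92, 0.436, −8.1e−5) for the reference tablet (the
coefficients are configuration so other devices can be calibrated; the
polynomial is only valid over the device range, roughly 57–1200
µmol m⁻² s⁻¹, and goes negative far outside it). Within the culture the
local intensity follows Lambert–Beer,

    I(z) = I0 * exp(-eps * X * z),

where `X` is the biomass concentration (g/L ≡ kg/m³) and `eps` [m²/kg] is
an effective extinction coefficient from Cornet's two-flux approximation:

    alpha = sqrt(E_a / (E_a + 2 b E_s)),    eps = (1 + alpha) / (2 alpha) * E_a,

with mass absorption `E_a`, mass scattering `E_s` and backward scattering
fraction `b`. Averaging the profile over the column gives the light the
"average cell" sees,

    I_avg = I0 * (1 - exp(-eps X h)) / (eps X h),

which decreases as the culture thickens (self-shading). Below an optical
depth of 1e−8 the code switches to the two-term Taylor expansion
`I0 (1 − eps X h / 2)` to avoid 0/0. An indicator with period 24 h gates
the light: on while `t mod 24 < L`, off otherwise, for `L` hours of light
per day. On/off switches are exact discontinuities and are treated as
integrator breakpoints, never smoothed.

**Kinetics and balances.** Growth follows a double Monod law in average
light and nitrate with a first-order death term:

    mu    = mu_max * I_avg/(K_I + I_avg) * c_N/(K_N + c_N)
    dX/dt = (mu - mu_d) X - (F_M/V) X
    dV/dt = F_M - F_S
    dc_N/dt = -Y_NX mu X - F_M c_N / V + F_M c_N_feed / V

Daily sampling removes 7.5 mL of culture and returns the same volume of
fresh medium. By default this is an impulsive event (biomass diluted by
`(V − V_s)/V`, nitrate mixed toward the feed concentration) at each
recorded sampling time, because the withdrawal is instantaneous on the
culture's time scale; the continuous `F_M = F_S` rate formulation above is
retained as an option, and the two converge as the per-event volume
shrinks. When nitrate crosses zero inside a step it is clamped to zero and
the nitrate Monod factor vanishes (the raw balance would undershoot).

## Units

Times in hours, concentrations in g/L, intensities in µmol m⁻² s⁻¹ (PPFD),
heights in m, volumes in L, optical coefficients in m²/kg. Biomass in g/L
is numerically identical to kg/m³, which is what makes `eps * X * z`
dimensionless; this is the only dimensionally consistent reading and is
fixed project-wide. `K_N` is stored in g/L. Note a unit tension in the
literature source of the default value: the nitrate half-saturation is
quoted both as 0.149 mg/L and (elsewhere) fixed as 0.15 g/L — a 1000-fold
discrepancy. The mg/L reading is the physically plausible one for a
half-saturation constant and is the package default (1.49e−4 g/L); the
discrepancy is surfaced here rather than silently resolved.

## Integration

Two paths share one event plan (breakpoints at light switches and sampling
events):

- **`lsoda` (default).** Segment-wise `scipy.integrate.solve_ivp` with
  LSODA, rtol 1e−8 / atol 1e−10, dense output. Output times are read off
  the dense interpolant, so internal stepping depends only on physical
  events and trajectories are exactly invariant under refinement of the
  output grid. A terminal event detects nitrate exhaustion; without feed
  the remainder of the segment is pure first-order decay and is evaluated
  in closed form.
- **`rk4` (estimation fast path).** Fixed-step classical RK4 with
  dt ≤ 0.25 h (refined 16× while `c_N < 0.02` g/L to resolve the sharp
  depletion corner), JIT-compiled with numba (pure-Python fallback). It
  agrees with the adaptive path to ~1e−7 relative on the campaign
  trajectories and is ~3 orders of magnitude faster, which is what makes
  the multi-start loops tractable on one CPU.

## Parameter estimation

The objective is the max-normalised sum of squares: for each dataset
(one observable of one flask), residuals are divided by the maximum
observed value of that dataset, squared and summed; datasets are then
summed. This reading ("residual over max, then squared") is
scale-invariant, which is what permits combining biomass and nitrate
series in one objective; the alternative reading (squared residual divided
by max) is available via `objective_mode="scaled"`.

The search is Nelder–Mead. Box bounds are imposed by mapping each bounded
coordinate through a sigmoid onto its open interval and running the
simplex in the unconstrained image, so all iterates respect the bounds
without penalty tuning. The default termination profile is the classic
simplex default (xatol = fatol = 1e−4, iteration and evaluation budgets of
200 per dimension) — deliberately so: several coordinates of this model
are weakly or not at all identified (see below), and under very tight
tolerances the simplex drifts along flat directions essentially
arbitrarily, while identifiable estimates change by less than 0.5%.
Tighter settings are available per call.

Estimation proceeds in three stages, because light attenuation and
substrate limitation both act on the growth rate and would be confounded
in a single fit:

1. **Light stage** — (E_a, E_s, b) fitted (unbounded, from the literature
   start 172 / 870 / 0.0008) to local-intensity scans at several heights,
   biomass concentrations and set intensities.
2. **Nitrate stage** — (mu_max, mu_d, K_I, K_N, Y_NX) fitted to the six
   flasks with nitrate analytics (settings 536 and 1200 µmol m⁻² s⁻¹,
   12 h light). One flask is a global held-out test set; the remaining
   five rotate through 4-train/1-validation splits, giving five runs. The
   reported value is the grand mean of the per-run means.
   Defaults: mu_max ∈ [0.02, 0.16] start 0.10; mu_d ∈ [0.0005, 0.002]
   start 0.001 (kept narrow: growth dominates death over the horizon, so
   wider bounds are not supported by the data); K_I ∈ [10, 120] start 64
   (bounded above near 100, from the observed half-saturation of measured
   growth rates); K_N ∈ [1e−5, 1e−2] g/L start 1.4e−4; Y_NX ∈ [0.03,
   0.75] start 0.15.
3. **Growth stage** — (mu_max, mu_d, K_I) over nine leave-one-out runs,
   one flask per light setting each, with stage-1/2 parameters fixed;
   starts at the stage-2 means, bounds at ±50%. The stage refuses to run
   without stage-1/2 results or explicitly configured fixed values.

Each run is a multi-start (default 100 restarts; the reduced profile used
in tests and the acceptance script is 10): per restart the ODE initial
concentrations (X0, c_N0) of the training flasks are re-sampled with 3%
relative Gaussian SD, emulating inoculum measurement error. Perturbing
the simplex start values instead is a separate option (used by the light
stage, which has no ODE initial state). All randomness flows from one
integer seed through `numpy` seed sequences, so every stage is exactly
reproducible.

## Identifiability — what the estimates do and do not mean

- **Effective extinction vs. (E_s, b).** The scan model depends on
  (E_a, E_s, b) only through `eps`, and `eps` only through E_a and the
  product `b·E_s`. The fit therefore pins E_a (≈0.2% at 3% noise) and the
  product, while E_s and b individually come to rest wherever the simplex
  path meets the flat ridge. Individual E_s/b values should be read as a
  parameterisation of `eps`, not as measurements.
- **K_N.** With daily sampling, the nitrate Monod factor differs from 1
  only within ~K_N (≈0.15 mg/L) of depletion — a window of minutes between
  two daily samples. Zero-noise synthetic experiments recover every other
  parameter to <0.1% while K_N slides to its lower bound; at 3% noise the
  estimate is upward-biased by roughly an order of magnitude (extra
  smoothing of the depletion kink absorbs noise, and the improvement is
  one-sided). K_N estimates from this design are not measurements of K_N.
- **mu_d.** Growth exceeds death by two orders of magnitude over the
  cultivation horizon; mu_d is reported but not meaningfully constrained
  beyond its (narrow) bounds.
- **mu_max–K_I ridge.** The two trade off strongly (doubling K_I is almost
  compensated by raising mu_max ~50%); the bounds anchor the pair, and
  widening the K_I bound lets both drift up the ridge together.

## Cross-validation and prediction bands

`run_loo_crossval` fits the growth stage over an explicit split plan (one
test flask per setting, never trained on — disjointness is asserted),
evaluates per-run validation R² and per-setting test R²/NRMSE, and emits a
simulated-vs-observed diagonal table plus Spearman rank correlations of
NRMSE against light intensity and duration. NRMSE is RMSE divided by the
maximum observed value, consistent with the estimation objective's
normalisation (mean- and range-normalised variants are options).

Prediction bands are pointwise empirical 5%/95% quantiles (numpy's default
linear interpolation) and the mean over `n_sims` (default 100)
trajectories, each with a parameter vector drawn uniformly with
replacement from the multi-start ensemble and initial concentrations
perturbed at 3% RSD; bands are bit-reproducible given the seed. The band
quantifies *trajectory* uncertainty. Because fitted parameter vectors are
mutually correlated (each reproduces the training data), the band is
narrower than the iid measurement noise of a fresh observation; measured
coverage of fresh 3%-noise replicate observations is ~0.6, not the nominal
0.9, and would only reach nominal if a measurement-noise term were added
on top — which the band procedure deliberately does not contain. The
diagonal comparison table uses band means (whether to use single
simulations instead was an open choice; means are stabler).

## Synthetic data

The generator emulates the reference campaign: nine light settings
(300–1200 µmol m⁻² s⁻¹, 12–24 h light/day) with parallel-flask counts
(6, 6, 6, 2, 3, 6, 2, 12, 12) — these sum to 55 although the campaign's
published summary says 54; the per-setting counts are taken as
authoritative and the discrepancy is recorded in the design notes.
Initial biomass 0.1 g/L exactly; observation at t = 0 and then every 24 h
to 240 h (≥180 h required, ~10 samples), each observation followed by the
7.5 mL sample-and-replace event; observations are model values ×
(1 + N(0, 0.03)), truncated at zero, with an independent spawned RNG
stream per flask (outputs are byte-identical per seed and independent of
generation order). Nitrate analytics cover the first three flasks of the
536/12 and 1200/12 settings. The initial nitrate concentration and the
feed nitrate level default to 1.0 g/L (the medium recipe level is not
public; 1 g/L is a typical nitrate level for Kessler-type media and
produces nitrate limitation at the high-light settings, as in the
experiments the nitrate data came from). The liquid height defaults to
h = 0.04 m for 200 mL working volume in a 500 mL conical flask — a
documented geometric assumption, the source never states it.

What the generator does not emulate: pigment acclimation and bleaching,
pH drift, CO₂/O₂ transfer, instrument drift, correlated or
flask-specific (inoculum) variability — replicates differ by iid
measurement noise only. Passing recovery tests on these data therefore
validates the estimation machinery under the model's own assumptions;
they say nothing about structural misfit to real cultures.

Light-scan fixtures use heights {0.01, 0.02, 0.03, 0.04} m, biomass
{0, 0.5, 1, 2, 4} g/L and set intensities {300, 750, 1200}; the X = 0
rows carry the incident-light regression information.

## Problem sizes and defaults in the shipped checks

The test suite and `scripts/acceptance.py` run the campaign at the design
above with the reduced 10-restart profile: the nitrate stage is 5 runs ×
10 restarts, the growth stage 9 runs × 10 restarts, bands 100 simulations.
These sizes were chosen so a full pipeline pass is a few minutes on one
core while the multi-start means are already stable to ~1%; the paper-scale
profile (100 restarts) is one config switch away.

## Known limitations

- Wavelength-resolved radiation, angular/3-D flask geometry and wall
  reflection are out of scope; the flat-panel analogy is the model.
- Temperature, pH, gas transfer and pigment dynamics are not modelled.
- The K_N and (E_s, b) estimates are not identifiable from this design
  (see above); the package reports them faithfully rather than
  constraining them to look identified.
- Nelder–Mead is local; the multi-start perturbs initial concentrations,
  not start vectors, so it probes noise sensitivity rather than global
  structure. Global or gradient-based optimisers are out of scope.
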