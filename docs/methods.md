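# Methods

## Photothermal model

A nanoparticle suspension under continuous-wave laser irradiation is treated
as a lumped thermal capacitance: one well-mixed mass `m_D C_D` (solvent mass
times specific heat, J/K) exchanging heat with the surroundings through a
Newtonian term `hS (T - T_surr)`, where `hS` (W/K) lumps the heat-transfer
coefficient and the container surface area. The energy balance is

    m_D C_D dT/dt = eta * I * (1 - 10^(-A808)) + Q_dis - hS (T - T_surr)

with `eta` the photothermal conversion efficiency (dimensionless, the
quantity of interest), `I` the delivered laser power (W), `A808` the
suspension absorbance at the 808 nm laser line, and `Q_dis` (W) the power
absorbed by the container and solvent alone. The closed-form solution is
exponential relaxation: heating approaches `T_surr + dT_inf (1 - e^(-t/tau))`
with `dT_inf = (eta I (1 - 10^(-A808)) + Q_dis)/hS`, and after laser-off the
temperature decays as a pure exponential with the same time constant
`tau = m_D C_D / hS`.

Inversion proceeds in the standard four steps. The cooling decay is
linearized through the driving-force ratio
`theta = (T - T_surr)/(T_max - T_surr)`, giving `t = -tau ln(theta)`; `tau`
is the slope of a least-squares regression of elapsed cooling time on
`-ln(theta)` forced through the origin (the model has no intercept). Then
`hS = m_D C_D / tau`, `Q_dis = hS (T_max,control - T_surr)` from a
solvent-only control run, and finally

    eta = [hS (T_max - T_surr) - Q_dis] / [I (1 - 10^(-A808))].

Assumptions worth stating: the suspension is spatially uniform (no
intra-sample gradients), `hS` is identical for sample and control (same tube,
same geometry), and the heating phase is long enough that the tail of the
heating trace approximates the steady state. Only temperature *differences*
enter every formula, so everything is done in degrees Celsius with no Kelvin
conversion; a test asserts invariance to a uniform time shift and to the
absolute ambient value.

### Numerical choices

- **T_max estimation** — mean of the last k = 5 heating-phase samples rather
  than the single maximum, to resist trace noise. `k` is configurable
  (`tail_points_k`).
- **Cooling-fit window** — points with `theta <= theta_min` (default 0.05)
  are dropped before the log-linear fit: near ambient the log transform
  amplifies noise without adding information. The first cooling point
  (`theta = 1`, `-ln theta = 0`) is retained but contributes nothing to a
  through-origin fit.
- **Steady-state guard** — if a control trace is still rising faster than
  0.01 degC/s at its end (slope estimated over the last 20 points, since a
  two-point difference would be noise-dominated), a non-fatal warning is
  attached to the fit.
- **Out-of-range efficiencies** — `eta` outside [0, 1] is reported unchanged
  with a flag, never clamped.
- **Exactness and the plateau** — the noiseless round-trip identity
  (simulate then analyze recovers `eta` to 1e-6 relative) requires the
  heating phase to actually reach its asymptote, because T_max is estimated
  from the trace tail; the exactness tests therefore heat for 20 time
  constants. At the default study conditions (600 s heating, tau ~129 s) the
  tail sits at 99% of the plateau, which biases `eta` by under 1% — well
  inside the stochastic recovery tolerance.
- **Laser power units** — the energy balance needs watts, but irradiance is
  usually quoted as a power density (1 W/cm^2 here). The system type stores
  watts; the config layer accepts `power_density_w_cm2 * beam_area_cm2` with
  the beam area defaulting to 1 cm^2.

## Drug loading and release

Loading is pure mass bookkeeping from UV-Vis measurements against a linear
standard curve: with `W_loaded = W_original - W_residual`,

    DLC = W_loaded / (W_loaded + W_nanoparticle)      (loading content)
    DLE = W_loaded / W_original                       (loading efficiency)

The standard curve is ordinary least squares with a free intercept
(plate-reader baselines are rarely zero); concentrations inverted from
absorbances are floored at zero with a flag, and estimates outside the
calibrated range are flagged as extrapolation. Drug-to-carrier mixing ratios
are treated as labels only — the arithmetic works in consistent mass units
throughout, since a molar ratio against a nanoparticle is not well defined.

Release experiments follow a sample-and-replace protocol: at each sampling a
volume `v` is withdrawn from the vessel (total volume `V`) and replaced with
fresh medium. The cumulative released mass at sampling `n` uses the standard
dissolution-testing correction

    M_n = V * C_n + v * sum_{i<n} C_i

— the drug currently in the vessel plus everything removed by earlier
withdrawals. This is an algebraic identity (mass conservation), tested as
such on random inputs, and it is order-sensitive: a naive `V * C_n` would
ignore the withdrawal history. Fractions divide by the loaded drug mass.
Noise-induced non-monotonicity in the fraction series is flagged, never
isotonic-regressed away. Condition endpoints are compared at a common time by
linear interpolation between samples.

## Bioassays

- **Hemolysis** — absorbance at 540 nm normalized between a PBS negative
  control (0%) and a deionized-water positive control (100%):
  `100 (ABS_s - ABS_neg)/(ABS_pos - ABS_neg)`. Affine-invariant in the three
  absorbances; out-of-range values flagged, not clipped; a plate whose
  positive control does not exceed its negative is rejected outright.
- **MTT viability** — blank-subtracted ratio of means,
  `100 (mean(treated) - blank)/(mean(control) - blank)`, with dispersion
  propagated from the treated-well replicate spread. The blank defaults to 0
  when no blank wells exist.
- **Tumor volume** — ellipsoid caliper formula `V = pi L W^2 / 8 * 4/3`
  (algebraically `pi L W^2 / 6`, i.e. (4/3)pi(L/2)(W/2)^2 with the width for
  both short axes). Length shorter than width warns about swapped axes but
  proceeds.
- **Relative trajectories** — each subject is normalized to its *own*
  baseline-day value, then group mean and SD are taken per day. Per-subject
  normalization (rather than normalizing group means) is the natural reading
  of "relative volume/weight in each group"; the baseline day is a parameter
  because studies differ on day 0 versus first-treatment day.
- **Group comparison** — two-sample pooled-variance Student t-test, matching
  the test conventionally named in animal-study statistics sections; Welch's
  form is available behind a flag. The 0.05 threshold is reported alongside
  every p-value, never applied silently. Two zero-variance groups with equal
  means return p = 1 by convention; unequal means with zero variance are
  flagged degenerate.

## Synthetic data: what it emulates, and what it does not

The generators produce every input stream with known ground truth, at
defaults chosen to be the study conditions the analyses target:

- **Thermal** — ambient 23 degC, plateau 54 degC (a 31 K rise), water-control
  rise 2.5 degC, thermal-camera noise 0.1 degC, 600 s heating + 600 s cooling
  at 1 Hz. With `m_D = 0.2 g` of water (`C_D = 4.18 J/g/K`) the 2.5 degC
  control rise fixes `Q_dis = hS * 2.5`; `hS = 0.0065 W/K` (tau ~129 s,
  consistent with a 5-minute plateau) and `A808 = 0.8` then make the target
  efficiency `eta = 0.22` reproduce the 31 K rise. The source publication
  never prints its `A808` or beam area, so the published 22% cannot be
  independently recomputed; here it is a generator truth that the analyzer
  must recover.
- **Release** — first-order saturation `F(t) = F_inf (1 - e^(-kt))` with
  24-h plateaus 0.13 (pH 7.4), 0.26 (pH 5.8), 0.68 (pH 5.8 + NIR) and 0.35
  (pH 7.4 + NIR, an assumption flagged in the truth record), and `k = ln(10)/12`
  per hour so 90% of the plateau is reached by 12 h. The kinetic form is a
  generator choice only — the analysis modules never assume it. Emitted
  concentrations are the exact inverse of the replacement correction, with
  absorbance noise mapped through the calibration slope. The loaded mass
  defaults to 10 mg (1 mg/mL drug in the 10 mL vessel).
- **Calibration** — 8 concentrations from 0 to 35 ug/mL, slope 0.02
  absorbance per ug/mL (the right order for doxorubicin's visible band at
  1 cm path), intercept 0.02, absorbance noise 0.01.
- **Tumor study** — 8 treatment groups x 4 animals, tumors starting at
  200 mm^3, per-group exponential growth (saline ~0.13/day through
  combination-therapy regression at -0.12/day), converted to caliper pairs at
  aspect ratio L/W = 1.5 with 0.3 mm caliper noise; body weight a mild random
  walk around per-group linear trends from 20 g.
- **Hemolysis** — truth rates drawn uniformly in [0, 4]%, inverted through
  the rate formula around controls at 0.1/0.9 absorbance.

Every generator is a deterministic function of (config, seed) via
independent, reproducible substreams, and each generator/analyzer pair is an
exact round trip at zero noise.

What the generators deliberately do *not* emulate: baseline drift or
convective transients in thermal traces, spectral overlap between drug and
nanoparticle absorbance, inter-animal growth-rate heterogeneity beyond
caliper noise, plate edge effects, or any spatial/imaging data. Passing
recovery tests on this synthetic data therefore demonstrates that the
*estimators are correct inverses under their stated noise model* — not that
real traces satisfy the lumped-capacitance assumptions.

## Known limitations

- `Q_dis` is estimated from a solvent-only control using the sample's `hS`;
  this is an approximation (the two runs share geometry but not contents).
- The permutation cross-check of the t-test agrees with the pooled-t p-value
  on average (mean absolute difference within 0.02 at n = 5 per group), but
  individual small-sample datasets can differ by more — the exhaustive
  permutation distribution at n = 3 has a granularity of 1/20, so extreme
  p-values cannot match.
- The cooling fit weights all retained points equally on the log scale;
  generalized least squares would down-weight the noisier late points but is
  unnecessary at the 0.1 degC noise level (stochastic recovery error ~0.003
  in `eta` at the study conditions, bounded at 0.02 in the tests).
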