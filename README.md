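# pttkit

Analysis toolkit for characterizing chemo-photothermal nanomedicines — the
class of experiments where a light-absorbing nanoparticle (e.g. a gold
nanorod in a metal-organic-framework shell) is loaded with a chemotherapy
drug, heated with a near-infrared laser, and evaluated from bench to animal.
It is aimed at experimentalists who have temperature traces, plate-reader
tables and caliper logs and want the downstream numbers computed
reproducibly: conversion efficiencies, loading and release percentages,
hemolysis and viability rates, and relative tumor-growth curves with
statistics.

## What it computes

**Photothermal conversion efficiency.** A laser-irradiated suspension is
modeled as a lumped thermal mass, m·C·dT/dt = η·I·(1−10^(−A₈₀₈)) + Q_dis −
hS·(T − T_surr). The cooling decay linearizes as t = −τ·ln θ with
θ = (T − T_surr)/(T_max − T_surr), giving the time constant τ and hence
hS = m·C/τ; the solvent-only control gives Q_dis; the efficiency follows as

    η = [hS·(T_max − T_surr) − Q_dis] / [I·(1 − 10^(−A₈₀₈))]

A forward simulator of the same balance (closed form, verified against
forward-Euler integration) supports round-trip validation.

**Drug dosimetry.** Beer–Lambert standard curves; loading content
DLC = W_loaded/(W_loaded + W_carrier) and efficiency DLE = W_loaded/W_original;
cumulative release with the sample-and-replace correction
M_n = V·C_n + v·Σ_{i<n} C_i.

**Bioassays.** Hemolysis normalized between PBS and water controls; MTT
viability; ellipsoid caliper volumes V = π·L·W²/6; per-subject-normalized
relative growth/weight trajectories; pooled Student t-tests.

**Synthetic data.** Every input stream can be generated with known ground
truth and realistic noise, so the full pipeline is testable end-to-end with
no external data.

## Worked example

Generate a complete synthetic study and fit the photothermal efficiency:

```sh
pttkit synth --seed 7 --outdir fixtures/
pttkit fit-ptt --sample fixtures/trace_sample.csv --control fixtures/trace_control.csv
```

```json
{
  "eta": 0.2176046454,
  "eta_out_of_range": false,
  "hS_w_per_k": 0.006493242715,
  "n_points_used": 385,
  "q_dis_w": 0.01620667771,
  "r_squared": 0.9987891458,
  "t_max_C": 53.69703687,
  "tau_s": 128.74923
}
```

The generated agent has a true efficiency of 0.22: from a trace with 0.1 °C
camera noise the fit recovers η̂ = 0.218, a cooling time constant of ~129 s
(so hS ≈ 0.0065 W/K for 0.2 g of water), and a container/solvent uptake
Q_dis ≈ 16 mW corresponding to the control's 2.5 °C rise.

Loading fractions from the drug mass balance (10 µg offered, 2 µg left in
the supernatant, 20 µg of carrier):

```sh
$ pttkit loading --original 10 --residual 2 --carrier 20
{
  "dlc_pct": 28.57142857,
  "dle_pct": 80.0
}
```

Cumulative release at 24 h per condition (`pttkit release --log
fixtures/release_log.csv --at-time 24`) yields fractions 0.129 (pH 7.4),
0.258 (pH 5.8), 0.673 (pH 5.8 + NIR) and 0.347 (pH 7.4 + NIR): acidic medium
roughly doubles release and laser heating more than doubles it again, the
on-demand behavior this class of carrier is designed for.

`pttkit report --config cfg.yml` chains all stages into one JSON report with
full provenance (inputs, parameters, seed, version) and deterministic
serialization. See `docs/methods.md` for the model, assumptions, and
numerical choices.

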