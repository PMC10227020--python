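# stressfiber

Mechanochemical simulation and analysis of a **minimal actomyosin stress
fiber**: two antiparallel bundles of semiflexible actin filaments anchored
by harmonic springs to two fixed focal-adhesion (FA) points, with
non-muscle myosin II motors (catch-bond unbinding, stalling force–velocity
walking) and α-actinin crosslinkers (slip-bond unbinding).  The package is
aimed at cytoskeletal biophysicists who want a desk-scale, fully scripted
model of contractility generation and the viscoelastic response of a
stress fiber to tensile pulling.

## Model in brief

Chemistry is sampled exactly with the Next Reaction Method: filament
(de)polymerization from a shared G-actin pool, crosslinker binding on
hinge-site pairs at 30–40 nm with unbinding rate χ·k_off·e^(F·x/kT),
motor binding/unbinding with rate k_off·e^(−F/F_c), and plus-end-directed
walking at (v₀/δ)(1 − F/F_stall).  Between chemistry slices the network
energy

E = Σ ½k(ℓ−ℓ₀)²  (cylinders, crosslinkers, motors, FA springs)
  + Σ k_b(1−cos θ)  (hinge bending)
  + excluded volume + boundary terms

is relaxed by conjugate-gradient minimization with analytic forces
(quasi-static mechanics).  Contractility is read out as the collective FA
spring force `F_FA` and energy `E_FA`; structure as the bundle-overlap
length `d_overlap` and the radial density `P(r)` of inter-filament
binding-site distances (normalized so ∫4πr²P(r)dr = 1).  The analysis
stage provides steady-state onset detection (window-estimator error
minimization), coefficients of variation, and log-space exponential /
power-law fits as Model-class objects with `fit()` and `summary()`.

Default parameters: 20 filaments per bundle, 23,000 G-actin, 48 NMII,
240 α-actinin, χ = 1, FA springs 1 pN/nm with 100 nm rest length, FA
separation 2750 nm in a 1×1×6 µm volume.  Polymerization constants are
calibrated from the pool fixed point so the bundles overlap by ≈600 nm
at the growth steady state (see `docs/methods.md`).

## Worked example

```python
import numpy as np
import stressfiber as sf
from stressfiber.experiments import plateau_stats, pull_response

params = sf.default_parameters().replace(seed=1, sync_dt=0.5)
state = sf.build_stress_fiber(params)
traj = sf.run(state, 600.0)               # ~3 minutes on one core

overlap, sd = plateau_stats(traj, "d_overlap", (400, 600))
force, _ = plateau_stats(traj, "F_FA", (400, 600))
rdf = sf.binding_site_rdf(state)
print(f"overlap plateau {overlap:.0f} +- {sd:.0f} nm, "
      f"F_FA {force:.0f} pN, P(r) peak at {rdf.argmax_r:.0f} nm")

pull_traj, before, after = pull_response(state, d_pull=100.0, relax=90.0)
df = pull_traj.to_dataframe()
e_ss = df.E_FA.iloc[-15:].mean()
fit = sf.fit_exponential_decay(df.t[1:], df.E_FA[1:],
                               t_pull=df.t.iloc[1], e_ss=e_ss)
print(fit.summary())
```

Output (seed 1):

```
overlap plateau 566 +- 32 nm, F_FA 136 pN, P(r) peak at 31 nm
Exponential relaxation fit (log-space linear regression)
  E_peak = 1.15e+04
  E_SS   = 1757
  tau    = 34.8 s  (95% CI 27 -- 49.1)
  RMSE   = 2036
  n      = 69
```

i.e. the fiber develops a ~600 nm overlap with a contractile force of a
few hundred pN, the binding-site pair density peaks at the α-actinin
length, and after a 100 nm pull the FA energy spikes several-fold and
relaxes back over tens of seconds.  Single-trajectory decay fits are
noisy; the standard protocol fits the ensemble mean over replicas, which
tightens the estimate to about 20 s on this configuration (see the
ensemble version in `tests/test_acceptance.py`).

A thin CLI wraps the same functions: `stressfiber run|pull|replay|rdf|
analyze|sweep|make-synthetic|calibrate` (see `--help`).

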