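# strutkit

Optical printability assessment for extrusion bioprinting.

When a hydrogel bioink is extruded onto a transparent substrate, three
things determine whether the print is usable: the geometry of the
deposited strut, how fast it keeps spreading after deposition, and how
the hanging filament between nozzle and substrate stretches under its
own weight. `strutkit` turns images of all three into numbers — for
bioink developers and bioprinting labs who want quantitative,
device-independent printability metrics without cell experiments.

## What it computes

**Strut geometry from pattern refraction.** A deposited strut takes a
parabolic cap profile h(x) = H·(1 − (2x/a)²). Acting as a cylindrical
lens over a diagonally striped background, it virtually rotates the
stripes; the apparent angle θ′ obeys tan θ′ = tan θ / M with
M = 1/(1 − z·ρ·Δn), which inverts to the vertex curvature ρ = 8H/a².
With the width a read from the strut edges, this yields H, the
cross-section κ = ⅔·H·a, and the throughput Q = κ·v_p — per station,
from a single bottom-view image.

**Spreading kinetics.** Strut width versus time is fitted with the
1/7-power wetting laws: complete wetting a(t) = K·(t/s)^{1/7}
(unbounded growth, water-based inks) and partial wetting
a(t) = a_s·(1 − e^{−Bt})^{1/7} (saturation, PBS-based inks), selected
by small-sample AICc. The initial-spreading prefactor a_s·B^{1/7} is
directly comparable with K, and K scales with ink viscosity as
K ∝ η^{−1/7}.

**Elongational viscosity from the hanging strut.** Balancing
elongational stress against gravity on the freely hanging filament
gives

    η_E = ( ρ_m·g / (dα/dx) − 2γ/d(s) ) / (dv/ds),   v(s) = 4Q/(π·d(s)²)

where α is the pitch angle, d(s) the local diameter (fitted with an
offset exponential decay), and the analysis is restricted to the
viscous stretching window before the diameter minimum. The output is
η_E versus strain rate ε̇ = dv/ds — extensional rheology measured
during printing.

A `synthetic` module renders ground-truthed scenes (striped bottom
views, side-view silhouettes, width/trajectory series) so the full
image-analysis chain is testable end to end.

## Worked example

```python
import numpy as np
from strutkit import (PrintConditions, analyze_trajectory, fit_partial_wetting,
                      initial_prefactor, model_selection)
from strutkit.synthetic import gen_spreading_series, gen_trajectory

# spreading of a water-based ink, sampled as in the experiments
t = np.linspace(0.5, 12.0, 24)
water, _ = gen_spreading_series("complete", {"K": 0.566}, t, noise_sd=0.01, seed=42)
sel = model_selection(water)
f = sel.complete
print(f"model: {sel.chosen}   K = {f.K:.3f} +/- {f.se_K:.3f} mm")

# PBS-based ink: saturating widths, initial-spreading prefactor
pbs, _ = gen_spreading_series("partial", {"a_s": 0.83, "B": 0.25}, t, noise_sd=0.01, seed=42)
pf = fit_partial_wetting(pbs)
print(f"a_s = {pf.a_s:.3f} mm   B = {pf.B:.3f} /s   a_s*B^(1/7) = {initial_prefactor(pf):.3f} mm")

# hanging strut at 5 mm/s and 0.25 mm^3/s, 1 px measurement jitter
cond = PrintConditions(v_p=5.0, Q=0.25, density=1000.0, gamma=0.0)
traj, _ = gen_trajectory(cond, d0=0.5, d_inf=0.22, s_c=2.5, alpha0=0.08,
                         m=0.12, s_max=8.0, n_points=320, noise_px=1.0, seed=42)
fit, curve = analyze_trajectory(traj, cond, include_gamma=False)
print(f"d(s): d0 = {fit.d0:.3f} mm, d_inf = {fit.d_inf:.3f} mm, s_c = {fit.s_c:.2f} mm")
print(f"eta_E: {curve.eta_E.min():.0f} - {curve.eta_E.max():.0f} Pa s over "
      f"eps_dot {curve.eps_dot.min():.3f} - {curve.eps_dot.max():.3f} /s")
```

prints

```
model: complete   K = 0.566 +/- 0.001 mm
a_s = 0.833 mm   B = 0.236 /s   a_s*B^(1/7) = 0.678 mm
d(s): d0 = 0.500 mm, d_inf = 0.222 mm, s_c = 2.45 mm
eta_E: 103 - 337 Pa s over eps_dot 0.239 - 0.785 /s
```

K is the ink's spreading prefactor (the strut width after one second);
its standard error comes from the fit Jacobian. The PBS ink's
a_s·B^{1/7} = 0.678 mm exceeding K = 0.566 mm means the PBS-based ink
initially spreads faster even though its width saturates. The
trajectory fit recovers the generating diameter profile within a
percent despite 1 px noise, and the decreasing η_E across the ε̇ range
is elongational thinning.

## Command line

```sh
strutkit spread extract snapshot.png --path-csv path.csv --v-p 5 --scale 0.025 --out series.csv
strutkit spread fit series.csv --model auto --out report.json
strutkit traj analyze side_view.png --conditions cond.json --out-dir results/
strutkit optics invert --apparent-angle 33.4 --config optics.json --width 0.8
strutkit synth scene.json --seed 7 --out-dir scenes/
```

Config files are JSON with units in the key names (`*_mm`, `*_s`,
`*_per_s`); unknown keys are rejected.

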