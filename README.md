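# cellcompass

Quantitative analysis of persistent single-cell migration, and a
minimal stochastic model — a "cell compass" — that explains it as a
two-sided feedback between protrusion dynamics and an internal
polarity axis.

Adherent cells such as RPE1 epithelial cells migrate persistently for
hours without external cues: protrusions form preferentially in front
of the internal polarity axis (read out by the nucleus→Golgi vector
and by polarized post-Golgi trafficking), and protrusions in turn pull
that axis toward themselves. `cellcompass` is written for cell
biologists and biophysicists who want to (a) quantify migration movies
— trajectories, morphodynamic edge-velocity maps, trafficking maps —
and (b) place their cells on the model's phase diagram by measuring
two effective feedback strengths.

## What it computes

**Trajectory statistics** (`cellcompass.trajectory`): direction
autocorrelation `AC(lag) = ⟨cos Δθ⟩` and the persistence time τ from an
`exp(−lag/τ)` fit; directionality ratio; the signed angle between the
nucleus→Golgi axis and the direction of movement, with circular
mean ± SD; reorientation curves and cumulative reorientation
fractions; and the alignment index, the mean resultant length
`r = √(⟨sin θ⟩² + ⟨cos θ⟩²)` of paired angle differences.

**Morphodynamic maps** (`cellcompass.morphomap`): each cell contour is
resampled to 100 equidistant markers; markers are paired between
frames by the total-least-squares circular shift, giving a
markers × time map of signed edge speeds (protrusion positive).
Columns can be recentred on any reference axis and averaged into mean
protrusion profiles.

**Trafficking maps** (`cellcompass.trafficking`): mean intensity along
rays from the Golgi centroid to each contour marker, cross-correlated
row-by-row against the morphodynamic map to extract the time lag by
which secretion follows protrusion.

**Segmentation and tracking** (`cellcompass.segmentation`): the
classic threshold → clear border → remove small → close → fill
pipeline, nearest-to-previous centroid tracking, and stage-jump
correction.

**The model** (`cellcompass.compass`): protrusive events (a calibrated
space–time template built from a Cdc42-response transfer function) are
nucleated with probability 0.25/frame — in front of the polarity axis
with probability `P_polarized`, uniformly otherwise — while the axis
moves as `dc/dt = κ·F_prot + (1 − κ)·F_basal`. Phase diagrams of
persistence time, protrusive unicity, and alignment over
`(P_polarized, κ)` serve as look-up tables; `estimate_parameters`
inverts them for measured observables.

**Synthetic ground truth** (`cellcompass.synthetic`): persistent
random walks with known τ, contour movies realising a known map,
trafficking stacks with a known lag, and blob images — every analysis
stage is testable without microscopy data.

## Worked example

```python
import numpy as np
from cellcompass import compass

# one simulated cell with strong two-sided feedback
res = compass.simulate(compass.CompassParams(p_polarized=0.8, kappa=1.0, seed=0))
print(compass.simulation_observables(res))
```

```
{'tau_hours': 3.78, 'tau_censored': False, 'unicity': 0.663, 'alignment': 0.803}
```

The simulated cell is strongly persistent (τ ≈ 3.8 h at 5 min/frame),
keeps close to a single protrusive front (unicity ≈ 0.66), and its
polarity axis tracks its direction of motion (alignment ≈ 0.80). The
same three numbers computed on a `p_polarized = 0, kappa = 0` cell
drop to 0.28 h / 0.53 / 0.03: without the feedback the model cell
jiggles without going anywhere.

Inverting the phase diagrams for a measured cell cohort:

```python
axis = np.linspace(0, 1, 11)
diagram = compass.phase_diagram(axis, axis, replicates=20, base_seed=1)  # ~6 min
est = compass.estimate_parameters(diagram, tau_hours=2.3, unicity=0.65, alignment=0.72)
print(est.p_polarized, est.kappa)
```

```
0.615 1.0
```

i.e. a cohort with a 2.3 h persistence time, unicity 0.65 and
alignment 0.72 is placed at `P_polarized ≈ 0.6–0.7` and `κ ≈ 0.9–1.0`:
most protrusions form in front of the polarity axis, and the axis is
almost entirely slaved to the protrusions. `est.contours` holds the
per-observable iso-lines for the crossing plot
(`cellcompass.plotting.plot_phase_diagrams`).

A command-line interface mirrors the main operations:

```bash
cellcompass analyze-track track.csv --dt-min 5
cellcompass simulate --p-polarized 0.7 --kappa 0.9 --seed 1
cellcompass phase-diagram --grid 11 --replicates 20 --seed 1 --out scratch/pd
cellcompass fit-params --diagram-prefix scratch/pd --tau-h 2.3 --unicity 0.65 --alignment 0.72
cellcompass traffic-xcorr stack.tif contours.csv map.csv --golgi-x 64 --golgi-y 64
```

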