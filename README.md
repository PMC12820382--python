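# fibrildeg

Tools for studying enzymatic degradation of tendon collagen fibrils at the
population level: phenomenological degradation models, the power analysis
used to plan incubation times, and a piecewise SEM image-analysis pipeline
(fibril diameter, alignment, curvature, D-band period) validated against a
synthetic image generator with known ground truth.

Tendon collagen fibrils form bimodal diameter populations — a small (S1) and
a large (S2) subpopulation — and collagenases such as MMP-1 remove material
from the fibril surface at a rate that depends on fibril size. Starting from
an empirically calibrated linear rule for the cross-sectional-area loss per
5 h of incubation,

```
ΔCSA = −65.94 + 0.0721 · CSA_i     [nm² per 5 h],   CSA = π d² / 4,
```

the package steps three models over a fibril population in 5-h increments
up to 25 h:

* **size-dependent** — each fibril loses its own ΔCSA, recalculated from its
  current area at every step;
* **subpopulation** — one average ΔCSA per S1/S2 cluster (k-means, k = 2),
  fixed at t = 0;
* **size-independent** — a single population-wide average ΔCSA, fixed at t = 0.

A one-sided two-sample power analysis converts a population's (SD, N) into
the minimum detectable mean-diameter difference Δ at a target power
(noncentral-t solution of `P(T > t_{1−α,df} | ncp = Δ/(s√(2/n))) = power`),
and the modeled cumulative-decrease curve is interpolated to the first whole
hour at which that effect is reached — the minimum useful incubation time.

On the imaging side, fibrils traced in SEM images are measured in 250-nm
pieces (perpendicular edge-to-edge widths at the steepest intensity
gradients, piece orientation from the endpoint chord), yielding per-fibril
mean/SD diameter, image-normalized alignment, curvature (cumulative |Δθ| per
µm), and the D-band period from the constrained (36–70 nm) peak of averaged
FFT power spectra of 5-px-wide axial intensity profiles.

## Worked example

```python
import numpy as np
from fibrildeg import population, degradation, powercalc

pop = population.sample_population(population.REFERENCE_MIXTURE, 416,
                                   rng=0, stratified=True)
split = population.cluster_subpopulations(pop, seed=0)
traj = degradation.run_model(pop, "size_dependent", hours=25, split=split)
t, curve = degradation.summarize(traj, split).curve("full")

effect = powercalc.min_detectable_effect(sd=49.7, n=416, power=0.95)
hours = powercalc.required_incubation_hours(t, curve, effect)
print(f"first 5-h mean decrease: {curve[1]:.2f} nm")
print(f"95%-power minimum effect: {effect:.1f} nm -> {hours} h of incubation")
```

prints

```
first 5-h mean decrease: 4.48 nm
95%-power minimum effect: 11.4 nm -> 14 h of incubation
```

i.e. a synthetic 416-fibril extensor population loses about 4.5 nm of mean
diameter in the first 5 h under the size-dependent model, and roughly 13–14 h
of incubation (the crossing sits almost exactly on the 13-h boundary, so the
whole-hour ceiling varies by a seed's sampling noise) are needed before an
11.4-nm decrease — the smallest difference detectable at 95% power with
these population statistics — can be expected.

The same pipelines are scriptable from the shell via the `fibrildeg` CLI
(`simulate-population`, `degrade`, `power`, `hours`, `simulate-image`,
`measure`, `dband`, `check`).

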