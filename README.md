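# cilgibbs

Spatial point-process analysis of contact inhibition of locomotion
(CIL) in tumour histology.

Tumour growth is a spatial birth-and-death process: cells divide and
die, and cells that maintain homotypic CIL keep a minimum distance `h`
from their neighbours.  Such a process converges to a **Gibbs
hard-core point process** with intensity `beta = m/d` (mitotic over
apoptotic rate) and hard core `h`.  Representing the cells of a
histology region as planar points, `cilgibbs` asks, patient by patient,
how close the observed pattern is to that inhibited equilibrium:

- **L-function**: Ripley's `K(r)` with edge correction, transformed to
  `L(r) = sqrt(K/pi)`; under complete spatial randomness `L(r) = r`,
  inhibition pushes `L` below the diagonal, clustering above.  The
  coordinate `L_r` is the radius where `|L(r) - r|` peaks.
- **Geyer saturation model**: a Gibbs model with interaction strength
  `gamma` (`< 1` inhibitory, `> 1` clustered), interaction radius `r`
  and saturation cap, fitted by maximum pseudolikelihood
  (Berman-Turner device); the fitted radius is the coordinate `G_r`.
- **Cohort stratification**: the per-patient inhibition metric
  `M(r) = (L_r, G_r)` is z-scored and split by k-means, with the number
  of groups chosen by a ten-index validity vote; the tighter cluster is
  the inhibited "Gibbs" group, the dispersed one the "Invasion" group.
- **Survival association**: the mean inhibition metric
  `MIM = (z_L + z_G)/2`, smoothed along increasing survival time and
  compared with a randomized ordering via a Fisher band test, locates
  the survival time at which homotypic CIL is established and splits
  the Gibbs group into LH-CIL (lost heterotypic CIL) and H-CIL
  patients.
- **Differential expression**: TMM-normalised negative-binomial GLM
  likelihood-ratio tests between LH-CIL and H-CIL samples, with
  RMS-normalised expression signatures and cell-movement direction
  counts.

A synthetic-data module generates every input the pipeline consumes —
hard-core / Poisson / Thomas point patterns, stained-nuclei images with
ground truth, phenotype-linked survival cohorts, and count matrices
with planted effects — so the whole analysis is testable end to end
without any external download.

## Worked example

Simulate a contact-inhibited tissue region at equilibrium and recover
its interaction structure:

```python
import numpy as np
from cilgibbs import Window, fit_geyer, estimate_K, l_metric
from cilgibbs.synthetic import BirthDeathParams, gen_hardcore_pattern

window = Window(0, 300, 0, 300)              # 300 um x 300 um region
params = BirthDeathParams(birth_rate=200 / window.area, death_rate=1.0,
                          hard_core=12.0, seed=42)
pattern = gen_hardcore_pattern(params, window)
print(f"simulated {pattern.n} cells, min NN distance "
      f"{pattern.min_nn_distance():.2f} um")

fit = fit_geyer(pattern)
print(fit.summary())

est = estimate_K(pattern, np.linspace(0.0, fit.r * 2, 256))
r_star, dev = l_metric(est)
print(f"L-function optimum: r* = {r_star:.2f} um, |L(r*) - r*| = {dev:.2f}")
```

Output:

```
simulated 112 cells, min NN distance 12.04 um
Geyer saturation process (maximum pseudolikelihood)
=======================================================
n points              112
interaction radius r  12.91 um (profiled)
saturation            3 (profiled)
hard core (min NN)    12.04 um
log pseudolikelihood  -583.9522
-------------------------------------------------------
                  coef   exp(coef)        se
log beta       -5.9768    0.002537    0.1132
log gamma      -1.4815      0.2273    0.2537
-------------------------------------------------------
gamma < 1: inhibition; gamma > 1: clustering
L-function optimum: r* = 11.95 um, |L(r*) - r*| = 11.95
```

The birth-death chain was run with a 12 um hard core; the fitted Geyer
interaction radius (12.9 um, `gamma = 0.23`: strong inhibition) and the
L-function optimum (12.0 um) both recover that distance — the agreement
of these two coordinates is exactly what marks a patient as belonging
to the inhibited Gibbs group.

## Command line

Every stage is also a subcommand of the `cilgibbs` CLI:

```sh
cilgibbs simulate pattern --kind hardcore --hard-core 12 --seed 1 --out pat.csv
cilgibbs lstat --pattern pat.csv --out curve.csv
cilgibbs fitgibbs --pattern pat.csv --out fit.json
cilgibbs simulate cohort --n-gibbs 40 --n-invasion 20 --seed 1 --out cohort/
cilgibbs cluster --cohort metrics.csv --seed 1 --out labeled.csv
cilgibbs associate --cohort labeled.csv --band-sd 4 --seed 1 --out assoc.json
cilgibbs de --counts counts.tsv --groups groups.csv --out de.tsv
cilgibbs run --config run.yaml          # full pipeline with manifest
```

`cilgibbs run` executes the stages of a YAML config in dependency
order and writes a manifest with every seed, parameter and output
checksum; re-running the same config reproduces every output bit for
bit, and any stage can restart from the previous stage's serialised
output.

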