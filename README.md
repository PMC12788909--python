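# atrosim

Finite-element simulation of progressive cerebral atrophy with
region-heterogeneous material parameters, on synthetic labeled brain
phantoms.

Cerebral atrophy — the slow loss of brain tissue with aging and
neurodegeneration — deforms the surrounding tissue, enlarges the
ventricles, and loads structures like the corpus callosum. A modeling
question with practical consequences is how finely the brain's
regional material heterogeneity must be resolved: does a simulation
with 17 distinct material regions predict meaningfully different
mechanics than one with 9, 4, 2, or a single homogeneous region?
`atrosim` provides the full pipeline to ask that question: a synthetic
brain phantom generator, an Ogden hyperelastic finite-element solver
with a multiplicative atrophy split, mechanical readouts, and the
paired statistics comparing the model variants. It is aimed at
computational biomechanics researchers who want a self-contained,
verifiable implementation that runs on a laptop.

## Model

Tissue is a one-term Ogden solid with energy split into isochoric and
volumetric parts,

    psi     = psi_iso + psi_vol
    psi_iso = (2 mu / alpha^2) (lb_1^alpha + lb_2^alpha + lb_3^alpha - 3)
    psi_vol = (kappa / 4) (J^2 - 1 - 2 ln J)
    kappa   = 2 mu (1 + nu) / (3 (1 - 2 nu))

with isochoric principal stretches `lb_a = J^(-1/3) lambda_a` and
Poisson's ratio 0.49 for anatomical tissue. Atrophy enters through the
multiplicative split `F = Fe Fa`, `Fa = theta^(1/3) I`, where
`theta = Ja` is the local volume fraction remaining; the stored energy
is the atrophy-weighted `psi0 = Ja psi(Fe)` and only `Fe` generates
stress. The atrophy measure evolves with a threshold-gated rate law
driven by a static misfolded-protein concentration field c:

    theta_dot = Gh          if c <  c_crit      (healthy aging)
    theta_dot = Gh + Gc     if c >= c_crit      (accelerated)

with class-wise rates in %/year: gray matter and hippocampus
(-0.1, -0.2), white matter (-0.15, -0.35). Quasi-static equilibrium is
re-solved at each time increment with Newton's method on trilinear
hexahedra (full 2x2x2 Gauss integration), the outer CSF surface held
fixed at the skull. Five readouts are computed per element —
displacement magnitude, principal stretches, maximum shear
`lambda_1 - lambda_3`, hydrostatic stress `tr(sigma)/3`, von Mises
stress — and compared between region schemes with the Wilcoxon
signed-rank test and Cohen's d
`d = (xbar_1 - xbar_2) / s_pooled` on exactly paired elements.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Run the five-variant heterogeneity experiment on one 24^3 phantom
(about 2-5 minutes on one CPU):

```python
from atrosim import PhantomSpec, run_family_experiment

report = run_family_experiment(
    PhantomSpec(grid_shape=(24, 24, 24), random_seed=7),
    horizon=20.0, dt=5.0, keep_runs=True,
)

run17 = report.runs[(0, "17R")]
last = run17.summaries.query("increment == increment.max()").set_index("region")
print(last.loc[["CC", "CR", "FC", "VENTRICLE"], "volume_change_pct"].round(2))
print(report.heatmap.loc["displacement", ["9R", "1R"]].round(3).head(6))
```

Output:

```
region
CC          -9.73
CR          -9.23
FC          -3.52
VENTRICLE   -6.13
Name: volume_change_pct, dtype: float64
variant     9R     1R
region
Am       0.994  0.443
CB       1.456  4.230
CC       0.218  6.938
CI       0.321  1.233
CR       0.142  1.139
CSF      0.088  0.070
```

Reading this: after 20 simulated years the white-matter structures
(corpus callosum -9.7%, corona radiata -9.2%) lose volume faster than
cortex (frontal cortex -3.5%), as their atrophy rates prescribe; the
ventricular cavities shrink less than the tissue around them, so their
*fraction* of brain volume grows — the mechanical signature of
ventricular enlargement. The heatmap columns give each region's mean
displacement difference from the fully heterogeneous 17R model, in
percent: the homogeneous 1R variant deviates more than the 9R variant
in most regions (the corpus callosum most strongly, 6.9% vs 0.2%) —
coarsening the material description degrades the predicted mechanics.

The same pipeline is scriptable from the shell:

```sh
atrosim phantom --grid 40 --seed 7 --out phantom.vtu
atrosim simulate --config cfg.yaml --scheme 17R --out run17
atrosim simulate --config cfg.yaml --scheme 1R  --out run1
atrosim compare --run-a run17 --run-b run1 --out cmp.csv
atrosim stats cmp.csv --out stats/
```

Each run directory contains an ASCII VTK time series (`step_*.vtu`
plus a `.series` index, viewable in ParaView), per-increment region
summaries as CSV, the resolved configuration, and a checkpoint
archive.

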