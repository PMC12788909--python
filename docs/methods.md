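# Methods

`atrosim` simulates progressive cerebral atrophy as quasi-static volume
shrinkage of a hyperelastic brain, and quantifies how much regional
material heterogeneity matters for the predicted mechanical state.
This note records the model, its assumptions, the numerical choices,
and what the synthetic phantom does and does not represent.

## Constitutive model

Brain tissue is modeled as an isotropic, nearly incompressible,
one-term Ogden solid. The strain energy splits into an isochoric and a
volumetric part,

    psi      = psi_iso + psi_vol
    psi_iso  = (2 mu / alpha^2) (lb1^alpha + lb2^alpha + lb3^alpha - 3)
    psi_vol  = (kappa / 4) (J^2 - 1 - 2 ln J)

with isochoric principal stretches `lb_a = J^(-1/3) lambda_a`,
`J = det F`. The bulk modulus is never an independent input; it is
always derived from the shear modulus and the initial Poisson's ratio,
`kappa = 2 mu (1 + nu) / (3 (1 - 2 nu))`. The default anatomical
Poisson's ratio is 0.49 (stress fields in brain simulations are known
to be sensitive to this choice; lower values stiffen deviatoric
response relative to volumetric and can raise regional stresses
substantially). Viscous effects are neglected: atrophy evolves over
years, far beyond tissue relaxation times. Anisotropy is out of scope.

The volumetric prefactor is implemented as `kappa/4` exactly; the
functional form `(J^2 - 1 - 2 ln J)` is convex in J with a minimum at
J = 1, so `psi >= 0` for any admissible state and `psi = 0` iff F is a
rotation. A one-term Ogden with `mu > 0` and strongly negative `alpha`
(the regime fitted for brain tissue) reproduces the tissue's
compression-tension asymmetry; at `alpha = 2` the law degenerates to a
compressible neo-Hookean model, which the test suite exploits as an
independent cross-check.

### Material parameters

Per-region parameters live in a CSV table (label, mu_kPa, alpha, nu,
provenance) shipped with the package and meant to be edited. The
shipped values are placeholders of physiological magnitude (mu of
order 1 kPa, alpha between roughly -12 and -24), chosen to be distinct
per region so that heterogeneity analyses are non-trivial; no analysis
in this repository depends on their exact values. The CSF shell is an
ultrasoft, compressible solid: `mu_CSF` is one tenth of the mean
cortical shear modulus, with `alpha = 2` and `nu = 0.3`. The
ventricles are not a separate fluid model; they carry the same
CSF-like material and do not atrophy, so ventricular "enlargement"
emerges from the deformation of the surrounding shrinking tissue. The
choice of `alpha` and `nu` for CSF is a documented assumption (only
the stiffness contrast and compressibility are physically anchored).

Coarser region schemes (9R, 4R, 2R, 1R) obtain their parameters as
volume-weighted arithmetic means of the 17R constituents, with kappa
re-derived from the averaged (mu, nu). When all constituents share a
value the average returns it exactly, so a homogeneous parameter set is
preserved bit-for-bit through coarsening.

## Atrophy model

Tissue loss enters kinematically through a multiplicative split of the
deformation gradient, `F = Fe Fa`, with an isotropic atrophy tensor
`Fa = theta^(1/3) I`. The scalar `theta = Ja = det Fa` is the local
volume ratio lost to atrophy (theta < 1 means tissue loss). Only the
elastic part `Fe = theta^(-1/3) F` generates stress; the stored energy
per unit original volume is the atrophy-weighted `psi0 = Ja psi(Fe)`.
Pushing `psi0` forward to the current configuration cancels `Ja` from
the Cauchy stress, which is therefore a function of the elastic state
alone — `Ja` still weights the internal-force residual through
`P0 = theta^(2/3) dpsi/dFe`.

The rate law distinguishes healthy from accelerated (disease-driven)
shrinkage per tissue class, gated by a misfolded-protein concentration
field c with a Heaviside threshold:

    theta_dot = Gh              c <  c_crit
    theta_dot = Gh + Gc         c >= c_crit

Default rates (%/year; negative = shrinkage): gray matter and
hippocampus (-0.1, -0.2), white matter (-0.15, -0.35); CSF and
ventricles are inert. The boundary case `c = c_crit` takes the
accelerated branch. Tissue classes of mixed structures are
configurable defaults: the brainstem chain (midbrain, pons, medulla)
counts as white matter, the cerebellum and the deep gray nuclei as
gray matter.

The concentration field is synthetic and constant in time (protein
spreading dynamics are out of scope): its center takes the x
coordinate of the brainstem centroid, the y coordinate of the
hippocampus centroid, and the z coordinate of the superior extent of
the hippocampal bounding box; c is 1 at the center and decreases
linearly with distance, reaching 0 at the farthest mesh boundary
point. `c_crit` has no published value; the default is 0.5 on the
normalized field and is exposed in the configuration.

Because c is frozen, `theta_dot` is piecewise constant in time and the
explicit Euler update `theta_{n+1} = theta_n + (rate/100) dt` is exact;
rates are converted from %/year to fractions before integration, and
linear (not compounding) accumulation is the deliberate reading of a
linear volume-loss trend. theta is stored per element, matching the
element-wise constant concentration. The default horizon is 100 years
in 1-year increments in the configuration schema; the test suite and
the acceptance script use 20 years in 5-year increments, which keeps a
full five-variant experiment within minutes on one CPU while producing
clearly resolved variant differences. Horizon and step are not stated
quantities of the underlying study design; they are configuration.

## Finite elements

The mesh is a voxel grid of 8-node trilinear hexahedra (1 mm edge by
default) carrying one region label per element. Equilibrium at each
increment is the stationarity of `sum_qp w theta psi(Fe(u))` with full
2x2x2 Gauss integration. Stress and consistent tangent are evaluated
spectrally from the principal stretches of Fe; coincident-stretch
limits of the tangent's shear coefficients are handled analytically
(l'Hopital form, switched below a 1e-6 relative gap). Both are
verified against finite differences to ~1e-9 relative error in the
test suite.

Boundary conditions: homogeneous Dirichlet on the outer surface of the
CSF shell (the inner skull surface — the skull is rigid), never on the
brain surface itself. Displacements are measured from the undeformed
pre-atrophy configuration. For traction-free verification problems
(free shrinkage) a 3-2-1 pin set removes rigid-body modes while
keeping homogeneous dilatation admissible.

Newton's method uses a backtracking line search on the energy
(Armijo), relative residual tolerance 1e-8, at most 25 iterations, and
automatic bisection of the theta increment (up to 8 levels) on
non-convergence or element inversion. None of these tolerances are
physically meaningful; they are solver hygiene.

Linear solves use a sparse LU factorization (SuperLU) that is reused
as a preconditioner for conjugate gradients in subsequent Newton
systems and refreshed lazily whenever CG stalls — along the
quasi-static path the tangent changes slowly, so one factorization
typically serves many solves. A `linear_solver="direct"` setting
forces a fresh factorization per iteration.

Full integration at nu = 0.49 with trilinear hexahedra risks
volumetric locking; full integration is nevertheless the default for
fidelity to the modeling choice it reproduces. An optional
mean-dilatation mode (`fbar=True`) replaces the volumetric part of F
by its element average as an escape hatch; its tangent is the local
tangent evaluated at the modified gradient (slightly inexact Newton),
and it is off by default. The verification problems in the test suite
(uniform shrinkage states) are representable exactly by the element
space and are locking-free by construction; locking would manifest in
strongly inhomogeneous states as overstiff response.

## Readouts

Five fields characterize the response, evaluated per element from
quadrature-averaged F and sigma: displacement magnitude (mm), the
principal stretches (square roots of the eigenvalues of `b = F F^T`,
descending), maximum shear `lambda1 - lambda3`, hydrostatic stress
`tr(sigma)/3` (negative = compression), and von Mises stress
`sqrt(3/2 s:s)` of the deviatoric stress. Regional summaries integrate
J for deformed volumes; volume fractions use the anatomical tissue
plus ventricles as denominator, excluding the outer CSF shell (the
shell's own volume change is reported separately); the fraction-change
convention is initial minus final. Region means are volume-weighted,
which on a uniform voxel mesh coincides with count weighting; whether
means should instead be count-weighted on non-uniform meshes is left
configurable in principle and flagged here.

## Heterogeneity comparison and statistics

All five variants run on the identical mesh with the identical atrophy
history — only the material table changes — so element-wise values are
exactly paired. Within-region stress/stretch distributions are far
from normal, hence the paired comparison uses the Wilcoxon signed-rank
test (zero differences dropped before ranking; exact null for n <= 25
without ties, normal approximation with continuity correction beyond;
all-zero differences return p = 1 by convention). At the n of whole
regions the exact/approximate distinction is immaterial. Practical
significance uses Cohen's d with the pooled Bessel-corrected standard
deviation, labeled by the conventional 0.2 / 0.5 / 0.8 cutoffs
(boundaries belong upward; the cutoffs themselves are the standard
convention, adopted because no other is specified). Percentage
differences always use the 17R run as reference; per-phantom
percentages and d values are averaged unweighted across phantoms. No
multiple-testing correction is applied.

## The synthetic phantom

Real studies of this kind run on MRI-derived, FreeSurfer-segmented
subject meshes. The phantom replaces those with a parametric anatomy
on the voxel grid: a brain ellipsoid whose outermost cerebral layer is
the cortical ribbon (five cortical labels split by simple angular
rules), corona radiata beneath, corpus callosum and the lateralized
deep nuclei (caudate, pallidum, putamen, thalamus, amygdala,
hippocampus) centrally, a midbrain-pons-medulla column and the
cerebellum inferiorly, paired ventricular cavities adjacent to the
deep structures, and a CSF shell of at least the requested number of
complete voxel layers (3 mm default) grown by binary dilation.
Nucleus placements carry a small seed-controlled jitter; with jitter
off the phantom is mirror-symmetric in x, which the test suite uses as
a symmetry oracle. Laplacian surface smoothing, used on real
anatomies, is deliberately skipped: the phantom is analytic and
smoothing would only add noise.

What the phantom preserves: the topological relations every analysis
here depends on (cortex outside, callosum central, ventricles
interior, brainstem inferior), nonzero element counts for all 19
labels down to 24^3 grids, and per-region volumes unequal enough to
make volume-averaged coarsening non-trivial. What it does not
represent: subject-specific geometry, cortical folding, realistic
region shapes or volume ratios, interface smoothness. Consequently,
passing tests demonstrate the correctness and the qualitative behavior
of the pipeline (shrinkage, ventricular enlargement, the
decreasing-heterogeneity trend), not quantitative agreement with any
subject cohort; published headline numbers from MRI-derived meshes are
not reproduction targets at phantom scale.

## Degenerate inputs and tie-breaks

- Inverted elements (det F <= 0) abort assembly and trigger theta
  substepping; at the API level they raise a dedicated error.
- Eigen-decompositions use the symmetric solver with descending sort;
  exact ties keep solver order.
- Empty regions are reported as absent rather than zero-divided; a
  zero reference mean marks the percentage difference undefined (NaN,
  excluded from heatmaps with a warning).
- Cohen's d on zero pooled spread: 0 for identical means, an error
  otherwise at the API level; the experiment pipeline records NaN for
  such (tiny-region) cases.
- theta reaching zero raises, asking for a shorter horizon.

## Problem sizes

Defaults used by the shipped tests and the acceptance script: phantoms
of 24^3 voxels (about 7,900 elements, 28,000 dofs) for experiments and
18^3 for solver-level tests, horizons of 5-20 years in 5-year
increments. A 40^3 phantom (about 35,000 elements) runs in minutes per
variant and is the intended demo scale.
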