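# Methods

This note documents the models implemented in `intervalrt`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
phantom study can and cannot show.

## Uncertainty model and scenario sets

Setup errors are rigid patient shifts δ = (δx, δy, δz) drawn from an
uncorrelated zero-mean 3D normal with per-axis standard deviations
σ = (σx, σy, σz) mapped to the left–right (LR), anterior–posterior (AP)
and inferior–superior (IS) axes.  The default σ = (5, 10, 5) mm reflects
the larger AP positioning uncertainty typical of prostate setups.

Two discrete scenario sets discretize this distribution:

* **Optimization set (13 scenarios):** the nominal scenario plus four
  single-axis shifts per axis at ±0.5σ and ±1.0σ.
* **Evaluation grid (125 scenarios):** the Cartesian 5×5×5 grid of
  per-axis offsets {−1.5, −0.75, 0, 0.75, 1.5}·σ.

Scenario probabilities are not prescribed by the sampling rule itself;
we take wₖ ∝ PDF(δₖ), renormalized over the finite set, for both sets.
Renormalization (rather than importance correction) was chosen because
the weights only ever appear as a discrete probability measure in
means, variances and DVH moments.  Planning and evaluation never share
a scenario set: evaluation functions require the set tagged
`"evaluation"` and raise otherwise, so results are always reported
against shifts the optimizer did not see (including diagonal and
±1.5σ shifts outside the optimization range).

## Interval dose model

For fluence x and scenario matrices D_k, the per-voxel dose interval is
center `d_c(x) = D_c x` with `D_c = Σ w_k D_k`, and radius
`d_r(x)_i = sqrt(Σ_k w_k ((D_k − D_c) x)_i²)` — the probability-weighted
standard deviation, computed in deviation form so round-off cannot
produce negative variances (any residual negatives are clamped at 0).

Materializing the per-voxel covariance quadratic form costs O(n·m²), so
the weighted deviation stack `E_k = √w_k (D_k − D_c)` is compressed by
an SVD along the **scenario axis**: eigendecomposition of the K×K Gram
matrix `G_ab = <E_a, E_b>` yields singular values σ_r and sparse mode
matrices Φ_r with

    d_r(x)_i² = Σ_r σ_r² (Φ_r x)_i² ,

exact at full rank (rank ≤ K) and monotonically under-estimating under
truncation (each dropped term is nonnegative).  Modes are retained up to
a cumulative variance-explained threshold, default 0.99.  On the default
phantom this keeps 6 of 13 scenarios' worth of information (variance
explained 99.4%).  Eigenvalues below 10⁻¹² of the largest are treated as
numerical zeros.  Other factorizations (e.g. per-mode rank-1 structure
over voxels × bixels) would compress further but lose the exact
full-rank reconstruction property; we prioritized the testable
invariant.

## Objectives

All plan models share one penalty table (structure, type, reference
dose, weight):

| structure | type | reference | weight |
|---|---|---|---|
| CTV | DoseMin | 78 Gy | 30 |
| CTV | SqDev | 78 Gy | 0.01 |
| CTV | MaxDVH | 81 Gy < 5% | 10 |
| CTV | DoseMax | 83.5 Gy | 100 |
| PTV (*) | DoseMin / MaxDVH / DoseMax | as CTV | 30 / 10 / 100 |
| body | SqOver | 39 Gy | 10 |
| ring 0–20 mm | MaxDVH | 83.5 Gy | 100 |
| ring 20–50 mm | MaxDVH | 78 Gy | 100 |
| bladder | MaxDVH | 60 Gy < pull | 2 |
| rectum | MaxDVH | 40 Gy < pull | 2 |

(*) PTV rows are active only in the margin-based model.  Penalties are
voxel *means* per structure, so weights are grid-resolution independent.
MaxDVH penalizes `max(d − d_ref, 0)²` on the violating voxels between
d_ref and the dose currently received at the allowed volume fraction
(the hottest allowed fraction is spared); with volume fraction 0 — used
for the ring rows, which specify no fraction — this reduces exactly to a
squared-overdose penalty.  The bladder/rectum volume fractions ("pull")
default to the V60Gy/V40Gy fractions achieved by a preliminary nominal
CTV-only optimization, so each robust plan is pulled toward the OAR
sparing an unconstrained plan would reach; both are configurable.

Model-specific composition:

* **nominal / ptv:** all terms on the nominal-scenario dose.
* **minimax:** log-sum-exp smoothed maximum of the per-scenario nominal
  composites, inverse temperature β = 10³ (the smoothed value exceeds
  the hard maximum by at most log K / β); the hard maximum is available
  for evaluation.  Smoothing keeps the analytic gradient exact.
* **interval:** ω_CTV · F_CTV (Bertoluzza term, above) replaces the CTV
  SqDev row, with ω_CTV defaulting to that row's weight 0.01; OAR terms
  act on the upper bound d̄ = d_c + d_r, CTV DoseMin on the lower bound
  d_c − d_r, CTV DoseMax/MaxDVH on d̄ — a conservative closure, since
  the table itself only fixes the OAR treatment.

Gradients are analytic throughout; the radius chain rule uses
∂d_r,i/∂x = Σ_r σ_r² (Φ_r x)_i Φ_r[i,:] / d_r,i, with the subgradient 0
taken at d_r,i = 0.

The default θ = 10 emphasizes robustness; θ = 0 reduces F_CTV to the
expected-dose squared deviation, and F_total is non-decreasing in θ at
fixed fluence by construction.

## Optimization

Projected quasi-Newton (scipy L-BFGS-B) on the box x ≥ 0, initial point
uniform fluence scaled so the mean CTV center dose equals the
prescription — deterministic and seed-free.  Defaults: 300 iterations
cap for workbench runs, projected-gradient tolerance 10⁻⁶ relative to
the initial objective scale.  An interior-point backend could be
plugged in through the same value+gradient interface but is not a
dependency.

## Toy dose engine and phantom

The dose engine is a parallel-beam (non-divergent) pencil-beam model:
bixel j contributes `exp(−μ·depth) · exp(−lateral²/2σ_pen²)` to voxel i,
with depth the in-body radiological path along the bixel's central ray
(sampled at half-voxel steps, linearly interpolated) and μ = 0.005/mm,
σ_pen = 3 mm, bixel width 5 mm.  Scenario matrices are *recomputed* with
the isocenter translated by −δ rather than interpolated from the
nominal dose grid, so shift consistency is exact and tests need not
disentangle interpolation error.  Entries below 10⁻⁴ of the column
maximum are dropped.  The bixel lattice is fixed per plan (covering the
PTV projection plus a margin and 3σ_pen pad) so the bixel count is
identical across scenarios and models.

Single-slice phantoms (nz = 1) are treated as the mid-plane of a field
that is long and uniform in IS: the penumbra acts in-plane only and IS
shifts leave the slice dose unchanged (while keeping their probability
weight).  Without this, a 3 mm penumbra in a one-bixel-row field would
let ±7.5 mm IS evaluation shifts zero the slice dose — an artifact of
the degenerate geometry rather than a property of any plan model.  The
IS bixel lattice likewise collapses to a single row for nz = 1.

The default phantom is a 60×60 single-slice grid at 3 mm spacing:
elliptical body (semi-axes 85×75 mm), ellipsoidal CTV (23×20 mm,
centered 10 mm posterior), bladder anterior and rectum posterior of the
CTV with ~3 mm gaps.  PTV margins are (7, 7-4, 7) mm — 7 mm anterior,
4 mm posterior — expanded as the union over CTV voxels of an
AP-asymmetric ellipsoid (the anterior/posterior semi-axis selected by
the sign of the AP displacement), which is exhaustively testable.
Rings are distance bands 0–20 mm and 20–50 mm from the targeted
structure's surface, grown from the CTV for the nominal/minimax/interval
models and from the PTV for the margin model (configurable).

## Evaluation

Per-voxel expected dose and standard deviation over the evaluation
grid; Δ_i = ((E(d_i) − p)/(c1·p))² + (std(d_i)/(c2·p))², robust iff
Δ_i < 1 (strict); RI = fraction of robust CTV voxels.  c1 and c2 are
genuinely free constants of the Δ score; we default both to 0.05 (a 5%
of-prescription tolerance per component) and surface them in every
report — absolute RI values are only comparable at fixed (c1, c2).
VxGy uses the closed threshold (dose ≥ x Gy).  DVH bins default to
0.1 Gy steps from 0 to 1.2·p; confidence-band DVHs report weighted mean
± one weighted standard deviation of the per-scenario volume curves,
with the nominal curve from the δ = 0 scenario.

## What the synthetic study shows — and does not

On the packaged phantom the four models reproduce the expected
qualitative structure: RI(nominal) < RI(PTV) ≤ RI(interval, θ=10) ≤
RI(minimax), with minimax paying the largest V40Gy rectum and V60Gy
bladder price, and the optimized CTV dose spread non-increasing in θ.
These are structural claims about the objectives and the pipeline, not
clinical claims: the phantom is a homogeneous 2D slice, the engine has
no scatter, divergence or heterogeneity, organ geometry is idealized,
and the OARs sit closer to the CTV than in typical patients (so
absolute VxGy values run high).  Absolute RI values additionally depend
on the free constants c1, c2.  Problem sizes (60×60 slice, ~150 bixels,
13 + 125 scenarios) were chosen so a full four-model comparison runs in
well under a minute; the code paths are identical for full 3D phantoms.

## Known limitations

- Rigid-shift errors only: no rotations, deformations, inter-/intra-
  fraction decomposition or range errors.
- The radius is a standard deviation, i.e. a symmetric spread measure;
  skewed dose-falloff distributions are summarized by two numbers.
- MaxDVH penalties hold the volume-fraction quantile fixed within one
  gradient evaluation (standard practice); the objective is therefore
  piecewise smooth and L-BFGS-B occasionally terminates at a kink.
- The biological realism of the penalty table (no EUD/TCP/NTCP) is out
  of scope.
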