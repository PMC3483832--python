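# Methods

## Problem and model

After a bronchoalveolar lavage (BAL), part of the instilled saline remains
in the lung parenchyma and resolves over roughly 24 hours. `lavatrack`
quantifies this process from serial breath-hold CT: each subject is scanned
at four time points (baseline, immediately post-lavage, 4 h, 24 h), each
time at two inflation levels (FRC and TLC). Two quantities are tracked in
a Lagrangian frame anchored to the baseline TLC lattice:

1. **Regional tissue (non-air) volume.** Lung CT intensity is modelled as
   a two-compartment air/tissue mixture. With anchors HU_air = −1000 and
   HU_tissue = 55, the tissue fraction of a voxel with intensity *I* is

   β(I) = (I − HU_air) / (HU_tissue − HU_air),  clamped to [0, 1],

   and the tissue volume of a region R is TV = Σ_R v(x)·β(I(x)) with v(x)
   the voxel volume. Through a transform h from the baseline lattice into a
   post-phase image, the same material region has
   TV_i = Σ_R v(x)·J(h(x))·β(I_i(h(x))), where J is the Jacobian
   determinant of h. TVC_i = TV_i − TV_0 measures retained fluid (mL) and
   TVCR_i = 100·TVC_i/TV_0 its ratio.

2. **Regional ventilation.** Within one phase, the FRC-to-TLC transform's
   Jacobian is a surrogate of local ventilation. The transform is estimated
   on the TLC lattice mapping into the FRC image, so J(h) is the FRC/TLC
   volume ratio and the reported ventilation map is 1/J(h), making
   inspiratory expansion > 1. To compare phases with different breathing
   efforts, each map is reduced to its empirical CDF ("rank") within the
   lung — rank is invariant under any strictly increasing rescaling of the
   map — and regional function change is the mean voxel-wise rank change
   RC_i = Rank_i − Rank_0.

## Registration

Both registrations parameterise h(x) = x + Σ φ_i B((x − x_i)/δ) with a
uniform cubic B-spline control grid and minimise, by bounded L-BFGS-B over
a coarse-to-fine pyramid:

* **Intra-phase (RTVP, FRC→TLC):** tissue content is conserved over a
  breath-hold pair, so the similarity is the sum of squared tissue volume
  difference (SSTVD), whose residual uses the relation
  v₁(h(x)) = v₂(x)·J(h(x)). Weights: χ = 1 on the vesselness term,
  γ = 0.01 on the regulariser.
* **Inter-phase (post TLC→baseline TLC, RIVP):** fluid violates tissue
  conservation, so the similarity is plain SSD after a monotone
  histogram-matching of the template onto the target (256-bin masked
  histograms, 128 quantile knots, piecewise-linear transfer). Weights:
  χ = 2, γ = 10.

Both modes add χ·SSVMD — the sum of squared differences of Frangi
vesselness maps (α = β = 0.5, γ_Frangi = 5, σ ∈ {0.5, 1, 2, 4} mm,
γ-normalised derivatives, per-image min–max rescaling to [0, 1] inside the
lung) — and γ·Σ‖∇²u‖², the squared component-wise Laplacian of the
displacement, evaluated analytically from B-spline second-derivative
kernels.

**Units of the cost terms.** The similarity residuals are computed on the
dimensionless tissue-fraction scale: the SSTVD residual per unit voxel
volume (β₂ − J·β₁) and the SSD residual divided by the 1055 HU air–tissue
span. This makes the weighting constants unit-free, makes pyramid levels
comparable, and — decisively — gives the Laplacian weight γ = 10 real
regularising power in the inter-phase problem; with raw HU² sums the
regulariser is ~10⁻⁶ of the similarity and the transform folds (J < 0)
around the bright fluid region. The public `cost_*` functions keep the
literal sums for inspection; the optimizer minimises the normalised form.

**Multiresolution and injectivity.** Images are downsampled by block-mean
factors of two, from ⅛ resolution to full; the control grid starts at four
times the finest spacing (default 8 mm) and is refined alternately by
exact cubic subdivision. At each level the optimizer moves each
coefficient at most 0.40·δ (a conservative rounding of the Choi–Lee
sufficient bound for cubic B-spline injectivity) from the level's starting
value. Bounding the *increment* rather than the absolute coefficient is
deliberate: cubic B-spline values are convex combinations of their
coefficients, so an absolute bound of 0.40·δ would cap the total
displacement at 0.40·δ per axis and make even modest respiratory motion
unrepresentable on an 8 mm grid. The incremental bound loses the formal
composition guarantee, so J > 0 is verified on the target lung mask of
every returned transform and reported (`RegistrationResult.min_jacobian`).

**Gradients and stopping.** All cost gradients are analytic: chain rule
through the B-spline tensor basis (separable weight matrices per lattice),
the exact gradient of the trilinear interpolant, and the cofactor
expansion of dJ/dφ. Optimisation stops at a relative cost change below
1e−5 or 200 iterations per level (limited memory 10). Ω, the union of the
target lung mask and the deformed template mask, is recomputed once per
level.

## Synthetic study generator

No imaging data are distributed, so a seedable phantom generator supplies
every pipeline stage with ground truth. The default phantom is a 96³
lattice at 2 mm spacing: an ellipsoidal lung (semi-axes 50/55/60 mm,
~0.7 L) of −850 HU parenchyma at TLC inside a soft-tissue body, a
three-level bifurcating vessel tree (0 HU, radii tapering from 4 mm) whose
branch points are the landmarks, and smooth material-attached parenchymal
density heterogeneity (Gaussian blobs, sd 0.03 in tissue-fraction units,
≈30 HU) — real parenchyma is textured, and a perfectly uniform phantom
would leave intensity-driven registration underdetermined between vessels.

Deformations are analytic and numerically invertible (Picard iteration):
the intra-phase map composes an anisotropic contraction (J ≈ 0.61, peak
displacement just under 10 mm, placing FRC parenchyma near −750 HU), a
fixed dorsoventral linear gradient of deformation amplitude
(0.004 mm⁻¹ — the gravity-dependent ventilation gradient that anchors
rank maps across phases), small random Gaussian-bump displacements
(0.5 mm), a per-phase global effort factor (1 / 0.85 / 0.95 / 1), and a
Gaussian suppression well over the lavage region (strength 0.35 / 0.15 / 0
at post0/post4/post24) emulating locally depressed function. Inter-phase
maps are small bump displacements (2 mm). Images at deformed states divide
the material tissue fraction by the local Jacobian, so per-voxel tissue
volume is conserved exactly up to interpolation and the SSTVD relation
holds at the ground-truth transform. Vessels clamp at β = 1 rather than
exceeding the mixture range.

Lavage fluid is a uniform tissue-fraction increment over the airspace
(non-vessel) voxels of a 22 mm sphere, scaled so the added tissue volume
equals the phase's fluid volume: 15, 7.5 and 1.5 mL by default, emulating
the observed ~14% → 7% → 2% whole-lung resolution pattern at phantom
scale. Gaussian HU noise (default 0; 20 HU emulates clinical
reconstruction noise) is added last; noise-free copies and all warps,
masks, landmarks and fluid volumes are attached as ground truth.

What the phantom does **not** emulate: airway trees and dark-tube
structures, lobar fissures, scanner reconstruction kernels and artifacts,
gravity-dependent fluid layering, cardiac motion, and segmentation error
(masks are exact). Passing tests therefore demonstrate correctness of the
algorithms under idealised geometry and the stated noise, not clinical
accuracy on real CT.

## Numerical and design choices

* Trilinear interpolation everywhere a transform samples an image; the
  out-of-bounds fill is −1000 HU (pure air, β = 0; vesselness fills 0).
* Tissue integrals are voxel-centre Riemann sums; HU outside
  [−1000, 55] clamp to the mixture range.
* The whole-lung tracking region is the lung mask eroded by one voxel:
  boundary voxels interpolate across the lung/chest-wall interface, which
  biases the warped tissue integral one-sidedly upward. Fluid recovery is
  additionally reported over the lavage sphere dilated by two voxels — a
  material region containing the deposited fluid with a margin for
  registration uncertainty; a subregion integral avoids accumulating the
  small whole-lung background drift of the inter-phase transforms.
* Empirical-CDF ties use the "≤" convention: a constant Jacobian field
  ranks 1.0 everywhere.
* Slab profiles split the lung-mask bounding box into 30 equal slabs along
  the chosen axis; empty slabs are NaN.
* Histogram matching is applied once, at full resolution, before the RIVP
  pyramid is built.
* Degenerate inputs (empty masks, non-positive baseline volume, constant
  regression predictor) raise typed errors rather than returning NaN.

## Problem sizes

The test suite exercises the full 96³ phantom for deformation recovery and
fluid tracking (seven deformable registrations shared across tests via
session fixtures; roughly 1.5–2 minutes per registration on one CPU), and
reduced 40³–48³ phantoms for the end-to-end pipeline and unit tests.

## Known limitations

* The inter-phase SSD term systematically absorbs a few percent of the
  fluid signal into deformation (the transform slightly "explains away"
  the bright region); measured whole-lung TVC underestimates the instilled
  volume, consistent with the regression slope below one in the reference
  study. Subregion integrals keep this bias within a few percent.
* The incremental injectivity bound does not formally guarantee a
  diffeomorphism; it is verified a posteriori.
* Frangi scale selection is nearly flat in σ at the stated sensitivity
  constants for high-contrast vessels (the structure term saturates);
  multiscale maximisation still localises vessels but the per-scale
  response is not a reliable radius estimator.
* Histogram matching assumes comparable intensity cohorts between phases;
  a very large lavage-bright cohort distorts the transfer near the top
  quantiles.
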