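# Methods

This note documents the models, conventions and numerical choices behind
`septumkit`, what the synthetic data do and do not emulate, and the known
limitations.

## Septal slab phantom and local frame

The phantom idealizes the interventricular septum as a rectangular slab
with a fixed local frame: x = circumferential, y = transmural (LV
endocardium at y = 0), z = longitudinal toward the base. The transmural
coordinate ρ ∈ [0, 1] is computed analytically (y divided by wall
thickness); no Laplace solve is needed on a rectangular domain. The helix
angle rotates the primary eigenvector from the circumferential axis toward
the longitudinal axis within the wall-tangent plane:

* ρ < f_LV (default 0.608): linear ramp from +57° (LV endocardium) to −40°
  (end of the LV-side layer),
* ρ ≥ f_LV: constant −84° (abrupt RV-side layer of apicobasal fibers).

The defaults are the measured three-specimen sheep averages (layer split
60.8/39.2% of the wall, endocardial orientations +57°/−84°). Tensor
eigenvalues default to (1.4, 0.9, 0.7)·10⁻³ mm²/s — mean diffusivity
1.0·10⁻³ mm²/s and FA ≈ 0.35, typical of fixed ex vivo myocardium; the
secondary eigenvector is transmural. The default slab is 12 × 18 × 12 mm at
0.6 mm isotropic voxels: the transmural extent matches the wedge thickness,
while the in-plane extent is kept small since every downstream statistic is
transmural.

Diffusion-weighted signals follow the single-tensor model with the
6-direction icosahedral scheme plus one b = 0 volume at b = 1,000 s/mm²
(the acquisition's direction set is not published; the icosahedral set is
the standard minimal-condition-number choice). Noise is Rician: the
magnitude of (S + ε₁, ε₂) with ε ~ N(0, S₀/SNR) per complex channel. The
default SNR of 20 is a realistic value for long ex vivo acquisitions.
The phantom does not emulate eddy currents, B₁ inhomogeneity, partial
volume at tissue borders, or curved anatomy — recovery results on it bound
what is attainable under noise alone, not under acquisition artifacts.

## Tensor estimation and metrics

The log-linear fit solves B·d = ln(S₀/Sᵢ) per voxel by ordinary least
squares (exactly determined with 6 directions; richer schemes reuse the
same path), with S₀ taken from the b = 0 mean. Voxels with non-positive
signal are flagged invalid and excluded, never imputed. With noiseless
data the fit is exact to rounding (~10⁻¹⁶ relative), so linear vs iterative
weighting is immaterial at 6 directions. Tensor averaging is log-Euclidean
(exp of the mean log), which avoids the eigenvalue swelling of Euclidean
means; non-SPD inputs fall back to the Euclidean mean and are flagged.
Affine reorientation uses the finite-strain rotation R = A(AᵀA)^(−1/2),
preserving eigenvalues. Eigenvectors are sign-fixed for display only; every
angle downstream is computed sign-invariantly.

## Fiber angles, axial statistics and layer detection

HA and TA are the signed angles of the primary eigenvector's projections
onto the wall-tangent (c–l) and c–t planes relative to the circumferential
axis, folded into [−90°, 90°]; positive HA points toward the base
(right-handed helix). SE/SA are the corresponding elevation/azimuth of the
tertiary eigenvector; the cited coordinate-system conventions are not
restated in full anywhere accessible, so these definitions are fixed
package choices, stated in every output header. The MDI is defined here as
the mean absolute dot product of v₁ with its in-mask 3×3×3 neighbors
(center excluded): 1 for perfect alignment, 0.5 for uniformly random
orientations.

Transmural profiles use **axial quantiles**: fiber orientations are
180°-periodic, so bin values are unwrapped into a half-turn window centered
on the axial mean direction (via the doubled-angle resultant) before
quantiles are taken. A naive median is biased near ±90° — noise wraps −84°
fibers to +88° and drags the median toward zero by several degrees — and
the axial treatment removes this entirely.

The layer detector is a single change-point on the binned median HA: the
bin boundary with the largest absolute (axial) jump, accepted if the jump
reaches 30°. The threshold separates the discontinuity (≈45–50° jump at
the measured angles) from the rule-based drift per bin (<7° at 25 bins)
with a wide margin on either side. Pipelines default to 25 bins for the
0.6 mm phantom (30 transmural voxels; more bins would leave empty bins),
while the function default is 50 for denser data. Specimen summaries are
arithmetic means, printed at one decimal for percentages and whole degrees
for orientations, matching the conventional table format.

## Tractography

FACT follows the fixed per-voxel primary eigenvector (no interpolation),
sign-aligned with the running direction, advancing 0.05 mm per step;
termination on FA < 0.1, step-to-step turn > 60°, or leaving the
mask/volume. Tracking is bidirectional with each half capped at 20 mm so
the concatenated track respects the 40 mm total cap (the cap's
per-direction vs total reading is ambiguous; total is chosen); tracks under
1 mm are discarded. The angle criterion is evaluated per step.

## Wedge geometry and rule-based fibers

The wedge is a structured grid with each cube split into five tetrahedra —
four corner tets and a central one — with the mirrored split on
odd-parity cubes so shared faces carry the same diagonal (conforming). At
21 × 18 × 35 mm and 0.3 mm this yields 511,058 nodes and 2,457,000
tetrahedra (≈0.5 M / ≈2.5 M). Rule-based fibers interpolate the helix
angle linearly in ρ and rotate the sheet direction about the fiber axis by
the interpolated sheet angle (composition order: fiber rotation first; the
source description names the endo/epi angles but not the order). Layer
scenarios overwrite elements with centroid ρ > 1 − depth (no partial
elements). UVCs are analytic on the slab; arbitrary biventricular UVC
generation is out of scope and UVC fields may be supplied.

## Electrophysiology

**Ionic model.** The 2004 ten Tusscher–Noble–Noble–Panfilov human
ventricular model (17 states), epicardial variant by default, with
Rush–Larsen gate updates, the model's conditional updates for the
calcium-dependent fCa and g gates, and the analytic rapid-buffering
calcium update, at Δt = 20 µs. The choice of the 2004 formulation over the
2006 revision is deliberate: with G_Kr and G_Ks reduced by 20% the 2004
epicardial cell reaches APD90 ≈ 290 ms (10th beat, 1 Hz; baseline
≈ 272 ms), i.e. "around 300 ms" as the target physiology demands, whereas
the 2006 model starts at ≈ 306 ms and overshoots to ≈ 332 ms under the
same modification. A plain-NumPy ODE right-hand side of the same model is
kept for cross-checks against generic integrators.

**Monodomain.** βC_m ∂V/∂t = ∇·(σ_m∇V) − βI_ion + βI_stim with the
per-axis harmonic mean σ_m = g_i·g_e/(g_i+g_e) rotated into the element
fiber frame (printed values: longitudinal 0.2390/0.8585, transverse
0.0382/0.1374 S/m). β = 1400 cm⁻¹ and C_m = 1 µF/cm² are framework-style
defaults; the CV tuning makes the velocity targets insensitive to them.
Discretization: P1 finite elements with lumped mass on the tet mesh (the
structured wedge reuses the same assembly), explicit diffusion + ionic
splitting at 20 µs. The instability guard aborts when the potential leaves
[−100, +80] mV, excluding nodes within a 2 ms grace window of their own
stimulus (a 100 µA/cm² transmembrane pulse legitimately overshoots locally).
Activation is the first −20 mV upstroke crossing, linearly interpolated in
time (the original threshold is unstated; −20 mV is a common choice).

**CV tuning.** Per-axis bisection of a multiplier on σ_m on a 2 cm strand
(planar stimulus, probes 5 mm apart across the middle) until the measured
CV is within 1% of target, with a second sweep per axis because the
off-axis conductivity contributes slightly to the planar wave. Tuning is
resolution-specific: the discrete CV depression at 0.6 mm is substantial
(0.3 mm-tuned scales under-propagate badly there, especially transversely),
so wedge runs at 0.6 mm use scales tuned on a 0.6 mm strand, and the strand
targets themselves are tuned and verified at 0.3 mm — the verification
values are what the acceptance script reports.

**Eikonal and R-E⁺.** Arrival times solve √(∇tᵀM∇t) = 1 with
M = v_f²ff ᵀ + v_s²ssᵀ + v_n²nnᵀ, by multi-source Dijkstra on an extended
lattice neighborhood (coprime offsets, default radius 2; radius 3 for
tighter angular accuracy) with edge weight √(eᵀM⁻¹e) — the segment length
in the inverse (slowness) metric. Graph restriction overestimates times by
a few percent off-axis. The hybrid reaction–eikonal scheme delivers a 1 ms,
100 µA/cm² foot pulse per node at its arrival time with diffusion retained;
it is meaningful on meshes whose native propagation is slower than the
prescribed velocities, where the foot leads and sets the sequence.

**Layer study and the diamond classifier.** The activation-pattern study
paces a 1.5 mm disc at the center of the RV-endocardial face (stimulus
100 µA/cm², duration 2 ms) of the wedge at 0.6 mm (0.3 mm available behind
a flag) for 40 ms — the largest closed isochrone leaves the face by then —
with the substrate fibers set to the measured septal average (+57° → −40°
across the wall; the constructed layer replaces the natural RV layer) and
scenario layers of 5–20% depth at −90°…+45°.

The front-shape classifier works on the isochrone contour of the face
activation map. Because the coarse-grid fronts have soft corners riding on
an anisotropic elliptical background, a raw curvature-peak count cannot
separate them; instead the contour is affine-whitened by its own second
moments — any ellipse maps to a circle, any diamond/parallelogram maps to
a square — and corners are counted as prominent maxima (≥1.5% of the mean
radius) of the whitened radius function. A front is classified as a
diamond when it has exactly four corners and the 4th angular harmonic of
the whitened radius exceeds 0.017, the geometric mean of the values
measured for an ideal discretized ellipse (0.004, pure lattice noise) and
an ideal square (0.070). Closed isochrones up to the first boundary
arrival are scanned and the most developed (largest harmonic) is reported.
Under these conditions the test suite classifies the layer-free control as
elliptical (two corners, harmonic at the lattice noise floor) and the 5%
and 10% layers at −90° as diamonds (four corners, harmonic well above
threshold).

## Material-point mechanics

Passive: Ψ = C/2(e^Q − 1) + k/2 ln²J with C = 1.6 kPa (kPa inferred from
the incompressibility penalty k = 650 kPa entering the same energy),
exponent coefficients from the canine orthotropic set
(b_ff = 8, b_ss = 6, b_nn = 3, b_fs = 12, b_fn = 3, b_sn = 3), stored in a
versioned JSON parameter file; the basal neo-Hookean stiffness is
c = 1 MPa. The second Piola–Kirchhoff stress is analytic,
S = C·e^Q (W∘E) + k·lnJ·(2E+I)⁻¹ with W the full coefficient matrix
(off-diagonals appearing twice reproduce the printed factor 2), and is
verified against central differences of Ψ to <10⁻⁶ relative error.

Active: the Land 2017 human contraction model (six ODEs: crossbridge
fractions S and W, their distortions ζ_s and ζ_w, calcium-bound troponin,
blocked tropomyosin) with the published human rates and the overrides
T_ref = 100 kPa and Ca50 = 0.9 µM. Integration is forward Euler with
internal substepping at ≤0.1 ms. Calcium is supplied in µM; the ionic
model's mM calcium couples through a factor 1000. Active stress is
T_a·ffᵀ + 0.4·T_a(ssᵀ + nnᵀ): the transverse fraction is split equally
between sheet and normal because "transverse" is not decomposed further in
the source description. Strain/stress region summaries report the mean and
the 25–75% band per f/s/n component — the interquartile band is the
outlier-robust spread summary. Quantities are Green–Lagrange strain and
PK2 stress, labeled as such (the alternative Cauchy reading is not used).

## Problem sizes and determinism

Default problem sizes are desk-scale by design: a 12 × 18 × 12 mm phantom
at 0.6 mm (12 k voxels), the wedge at 0.6 mm (66 k nodes, 0.3 M tets) for
activation studies, 0.3 mm strands for CV work; the full 0.3 mm wedge
(0.5 M nodes) is constructed for the mesh census and available everywhere
via the resolution flag. All noise flows from a single integer seed
(NumPy Generator); equal seeds give bitwise-identical volumes and
byte-identical reports.

## Known limitations

* The phantom is rectangular; curved/biventricular anatomy, regional
  quadrant subdivision on real geometries, and acquisition artifacts are
  not modeled.
* The eikonal solver is graph-based (first-order, slight overestimate);
  it is a cross-check and R-E⁺ driver, not a reference arrival solver.
* Mechanics is material-point only: no 3-D finite-element solve, no
  circulation coupling, no pressure–volume loops.
* The MDI and SE/SA definitions are this package's operational choices
  where the cited originals are not fully specified.
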