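# septumkit

Tools for studying the **dual-layer fiber architecture of the
interventricular septum** and its electromechanical consequences.

High-resolution ex vivo diffusion-tensor MRI of large-mammal hearts shows
that the septum is not the smooth, rule-based transmural fiber rotation of
the classical left-ventricular free wall: about the outer third of the wall
on the right-ventricular side carries an abrupt layer of apicobasal
(downward-pointing) fibers, with the helix angle dropping suddenly from the
LV-side ramp to near −90°. `septumkit` provides a complete, synthetic-data-
driven pipeline to quantify that architecture and to simulate what it does
to electrical activation and to myocardial stress, for researchers in
cardiac imaging and computational electrophysiology/mechanics:

* **Phantoms** — diffusion-tensor phantoms of a dual-layer septal slab with
  exact ground truth, forward-simulated diffusion-weighted images
  (S = S₀·e^(−b·gᵀDg), 6 directions at b = 1,000 s/mm², Rician noise).
* **DTI** — log-linear tensor estimation, eigen-metrics (λ₁ ≥ λ₂ ≥ λ₃, ADC,
  FA = √(3/2)·‖λ−λ̄‖/‖λ‖, cFA), log-Euclidean tensor averaging and
  finite-strain reorientation for template building.
* **Fiber architecture** — helix/transverse/sheetlet angles (HA, TA, SE,
  SA) in the local cardiac frame, the myoarchitectural disarray index (MDI,
  mean |v₁·v₁′| over a 3×3×3 neighborhood), transmural profiles with axial
  (180°-periodic) statistics, change-point detection of the layer boundary,
  and per-specimen summary tables.
* **Tractography** — deterministic FACT streamlines on the primary
  eigenvector field (FA stop 0.1, max turn 60°, step 0.05 mm, length
  1–40 mm), HA/cFA coloring, TCK and VTK output.
* **Geometry** — a structured septal wedge (21 × 18 × 35 mm, five
  tetrahedra per cube with alternating parity; ≈0.5 M nodes and ≈2.5 M
  tets at 0.3 mm), Laplace–Dirichlet/rule-based fiber generation
  (α(ρ) = α_endo(1−ρ) + α_epi·ρ, sheet angle likewise), RV-side layer
  scenarios, inverse-distance mapping of measured angles, and UVC-range
  region carving (layer20/30/40 presets).
* **Electrophysiology** — monodomain reaction–diffusion
  (βC_m ∂V/∂t = ∇·(σ_m∇V) − βI_ion + βI_stim, P1 finite elements, lumped
  mass, operator splitting at 20 µs) with the 2004 ten Tusscher human
  ventricular ionic model (G_Kr and G_Ks scaled ×0.8 for the sheep-like
  ~300 ms action potential), conduction-velocity tuning to 75/30 cm/s,
  an anisotropic eikonal solver, the hybrid reaction–eikonal (R-E⁺) foot
  stimulus, and a diamond-shape classifier for activation isochrones.
* **Mechanics (material point)** — the orthotropic Fung-type passive law
  Ψ = C/2(e^Q − 1) + k/2·ln²J with
  Q = b_ff E_ff² + 2b_fs E_fs² + 2b_fn E_fn² + b_ss E_ss² + b_nn E_nn² +
  2b_sn E_sn², its analytic second Piola–Kirchhoff stress, the neo-Hookean
  basal material Ψ = c(I₁−3) + k/2·ln²J, the six-ODE Land active-tension
  model T_a = h(λ)(T_ref/r_s)[(ζ_s+1)S + ζ_w W] with a 40% transverse
  tension fraction, and f/s/n strain–stress mean/IQR summaries.

## Worked example

Generate a noisy phantom parameterized by the measured sheep averages
(layer boundary at 60.8% of the wall, +57° on the LV endocardium, −84° on
the RV endocardium), fit tensors, compute angle maps and detect the layer:

```bash
septumkit fibers --seed 1 --snr 20 --out-dir runs/demo --no-tracks
```

prints

```
discontinuity=True rho*=0.6 lv%=60.0 rv%=40.0 lv_endo=54.7 rv_endo=-84.4
```

i.e. from diffusion-weighted images at SNR 20 the pipeline recovers the
layer boundary at ρ* = 0.60 (true value 0.608; the 25-bin profile resolves
it to the nearest 0.04), an LV/RV layer split of 60/40% of the wall, and an
RV-endocardial fiber orientation of −84.4° against the ground-truth −84°.
`runs/demo/` then contains the NIfTI angle and MDI maps, the transmural
helix-angle profile (`ha_profile.tsv`), the layer report and a manifest
that makes the run reproducible byte-for-byte.

The electrophysiological layer study (activation isochrones on the RV
surface of the wedge, monodomain at 0.6 mm) runs as

```bash
septumkit ep --layer-depth 0.05 --layer-angle -90 --resolution-um 600
```

and classifies the resulting front shape: a thin apicobasal layer over the
measured septal substrate produces a four-cornered, diamond-shaped front,
while the layer-free control stays elliptical.

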