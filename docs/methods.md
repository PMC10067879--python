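# Methods

This note documents the models implemented in `ivusffr`, the assumptions
behind them, the numerical choices, and what the synthetic phantoms do and
do not establish about clinical data.

## Problem setting

Fractional flow reserve (FFR) is the ratio of the pressure distal to a
coronary lesion to the aortic pressure under maximal hyperemia; FFR ≤ 0.80
marks a lesion as ischemia-causing. Measuring it requires a pressure wire.
A *virtual* FFR is computed instead from anatomy: here, from an
intravascular-ultrasound (IVUS) pullback, which yields one lumen
cross-section per frame at known arclength spacing (pullback speed ÷ frame
rate) but does not image the side branches that bleed flow off the main
vessel. The package's core is the combination of a single-tube reduced-order
pressure solver with bifurcation *fractal laws* that estimate, from the
diameters visible in the pullback, how much flow each unimaged side branch
removes.

## Reduced-order pressure model

The vessel is the 1-D profile `A(s)` (lumen area, mm², `s` arclength from
the proximal inlet). Flow is steady and piecewise constant between
junctions. Pressure is marched proximal → distal with a standard
Young–Tsai-type per-segment closure:

* viscous term, integrated over every piece:
  `ΔP_v = ∫ 8πμ Q / A(s)² ds` (trapezoidal rule; equals Hagen–Poiseuille
  exactly on a uniform tube and converges at O(ds²) on tapers);
* expansion (Bernoulli jet) loss, charged **once per detected stenosis** at
  its distal recovery point:
  `ΔP_e = (ρ K_t / 2)(Q/A_d)² (A_d/A_s − 1)²`, `A_s` the throat area,
  `A_d` the recovery-point area. Charging per lesion rather than per sample
  avoids double-counting smooth tapers.

Defaults: μ = 0.0035 Pa·s, ρ = 1050 kg/m³, K_t = 1.0; SI internally, mmHg /
mm / mL·s⁻¹ at interfaces with 1 mmHg = 133.322 Pa. The exact discretization
used by the clinical study this design follows is not public; the closure
above is the common choice for pressure-drop virtual FFR and is validated
here against its own closed forms, not against that study's solver.

Boundary conditions: inlet pressure = mean aortic pressure `Pa`; inlet
velocity = hyperemic velocity, either given directly or derived from TIMI
frame counting (`v_rest = path_length × frame_rate / frame_count`) times a
configurable hyperemia factor (default 2.0 — published rest→hyperemia
conversions vary and the package treats the factor as a free parameter).
The outlet is fully developed flow: no outlet resistance. Consequence: flow
through a lesion does **not** fall as the lesion worsens, so a vessel whose
predicted distal pressure reaches zero is outside the model's validity (the
solver raises rather than returning a value).

## Bifurcation fractal laws

At a labeled junction the pullback provides the mother diameter `D_mov`
(median effective diameter over a 2 mm window just proximal of the node)
and the main-branch diameter `D_mb`. The side-branch diameter solves the
selected law, and the flow splits by the law's flow rule:

| law | diameter relation | flow rule |
|---|---|---|
| HK | D_mov^(7/3) = D_mb^(7/3) + D_sb^(7/3) | Q ∝ D^(7/3) |
| Murray | D_mov³ = D_mb³ + D_sb³ | Q ∝ D³ |
| Finet | D_mov = 0.678 (D_mb + D_sb) | Q ∝ D (interpretation) |

For the power laws the main-branch share reduces to `(D_mb/D_mov)^k`.
Finet's relation carries no flow rule of its own; the linear rule is the
simplest consistent choice and is flagged as this package's interpretation.
Measured `D_mb` at or above a law's bound (possible with noisy data) is
clamped to 0.99× the bound with a warning (strict mode raises).

## Explicit-branch comparator

The comparator builds the model the fast method is meant to replace: a
uniform stub (default 5 mm) per junction, hung at the junction's distal
boundary, and a network solve over main-path edges with the same
viscous+expansion closure (`ΔP = μ g_v Q + ρK_t g_e Q²`). Two outflow
closures:

* **murray_flow** (default): at each junction the stub demands
  `D_sb³/(D_mb³ + D_sb³)` of the incoming flow — Murray's law applied as
  distal-bed demand, the common prescribed-outflow closure in coronary CFD.
  Non-circular with respect to the single-tube HK split (exponent 3 vs 7/3),
  so their agreement on HK-consistent phantoms (Pearson r > 0.99, mean
  |Δdistal vFFR| ≈ 0.01 on the default suite) is an empirical result, not an
  identity.
* **resistance**: Thevenin terminals `R = C/D³` to zero venous pressure,
  the common constant `C` calibrated by 1-D root finding so total inflow at
  `Pa` matches the prescribed hyperemic inflow; the quadratic network is
  solved by a damped Jacobi–Newton fixed point (damping 0.5, tolerance 1e-8
  on relative flow updates, ≤200 iterations). This closure was implemented
  first and measured: because calibration forces the full inflow through
  the tree, flow reroutes around lesions into the side branches, biasing
  the comparator's vFFR high by ≈0.03 and dropping its correlation with
  the single-tube method to ≈0.8. That behaviour contradicts the observed
  near-equality of the two approaches on clinical data, so the resistive
  closure is retained as a sensitivity variant, not the default.

On a branchless vessel both closures reduce exactly (≤1e-10) to the
single-tube march.

## Stenosis detection

The healthy reference lumen is a per-vessel robust taper line: iterate
{fit `r(s)` linearly on inliers; drop samples below 0.9× the fit} to
convergence (≤20 iterations); if fewer than half the samples remain, fall
back to a constant 95th-percentile reference with a warning. On bifurcated
vessels the known caliber step-down `D_mb/D_mov` per labeled node (ramped
over 1 mm) is divided out before fitting and multiplied back into the
reference — without this, everything distal to a near-symmetric branch
(step ≈ 0.74) would read as stenotic. Samples below `(1 − 0.20) × r_ref`
are stenotic; runs closer than 2 mm merge; boundaries extend to the nearest
samples with `r ≥ 0.95 r_ref`; `%DS = 100(1 − d_throat/d_ref)`. All three
thresholds are configuration keys. A population-based healthy-vessel
template (as used clinically) is not reproducible here; the per-vessel fit
is the standard reference-lumen substitute and is what the phantom recovery
study validates.

## Adversarial segmentation

The segmentor is a fully convolutional encoder–decoder (4×4 stride-2
encoder convolutions, nearest-neighbour ×2 upsampling with 3×3 stride-1
decoder convolutions, U-net skip connections, sigmoid head over two output
channels: lumen and media–adventitia). The critic mirrors the encoder.
Both train on the masked-image multiscale L1 objective: per labeled frame,
the input multiplied by the predicted mask and by the ground-truth mask are
passed through the critic, and the loss is the mean over critic layers of
the per-element mean absolute feature difference. The segmentor descends
this loss, the critic ascends it, alternating 1:1 (Adam, lr 2e-4, β =
(0.5, 0.999)); critic weights are clipped to ±0.05 after each ascent step,
the usual stabilisation for feature-matching min-max objectives.

Implementation choices worth knowing:

* The raw masked image is the level-0 "feature", so a critic with zero conv
  layers is the identity critic and the loss is plain MAE — a useful exact
  reduction for testing, and a stabilising anchor during min-max training.
* Network inputs are standardized per frame (zero mean, unit variance).
  With raw [0,1] intensities a dark target region (the lumen in IVUS) makes
  the all-zero mask a cheap local minimum of the masked-image L1, and
  roughly half of random initialisations collapsed into it; standardization
  gives every region O(1) magnitude and removed the collapse across all
  tested seeds.
* Default widths are 8/16/32 (depth 3) for both networks — sized so a
  CPU-only overfit run on ten 64×64 frames reaches Dice > 0.9 in a few
  hundred alternating steps and stays well inside a ten-minute budget at
  2000 steps.
* Training at clinical scale (hundreds of thousands of frames) is out of
  scope; the module's contract is the loss and training mechanics,
  verified by overfitting its own training frames. Inference thresholds
  probability maps at 0.5, keeps the largest connected component, and
  extracts the boundary polygon in mm (marching squares); empty masks are
  flagged and their areas interpolated downstream.

## Synthetic phantoms

The phantom generator is the package's data source. Radius profiles are
multiplicative: a linear taper, times Gaussian (σ = extent/4) or clipped
cosine stenosis dips, times a smooth (1 mm smoothstep) caliber step-down
`D_mb/D_mov` distal to each bifurcation whose daughter diameters satisfy
the chosen law exactly. `main_fraction` scales `D_mb` relative to the
symmetric split; values above 1 (side branch smaller than the main — the
anatomically common case) are allowed up to the law's bound. Rendered
frames are a bright media–adventitia annulus (wall thickness 0.5 mm) around
a darker lumen disk with multiplicative Gaussian speckle; masks are exact
rasterized disks. Analytic contours are radius-corrected so polygon area
equals the true disk area, making the contour → centerline round trip exact
to float precision.

The standing evaluation suites (in `ivusffr.suite`) draw once from ranges a
coronary physiologist would call typical: 50–80 mm analysed length,
1.6–2.1 mm inlet radius, taper 0.004–0.010 mm/mm, one or two stenoses of
30–70 %DS (the angiographic inclusion range for physiology testing), one or
two bifurcations with `D_sb/D_mb ≈ 0.7–1.1`, `Pa` 85–100 mmHg, resting
velocity 100–160 mm/s doubled under hyperemia. Draws whose single-tube
solve predicts non-positive distal pressure are redrawn: the fixed-inflow
closure cannot represent flow-limiting lesions, and such vessels fall
outside the population in which FFR is measured. The detector-recovery
suite uses single-lesion tapered vessels with 2 % multiplicative radius
noise on the measured contours.

What the phantoms do **not** emulate: ultrasound physics (no ray tracing,
speckle statistics are Gaussian, no NURD/motion artifacts, no guidewire
shadow), vessel curvature (the solver is 1-D in arclength, so none is
needed), plaque composition, and inter-observer contour variability beyond
isotropic radius noise. Passing the phantom suites therefore demonstrates
the *mechanics* — solver correctness against closed forms, law algebra,
detector recovery, training dynamics, method agreement — not clinical
diagnostic performance, which requires patient data this package does not
ship.

## Numerical details and degenerate inputs

* Pieces tile the vessel exactly; boundary samples are shared (interpolated
  areas), so piecewise trapezoidal integrals sum to the whole-vessel
  integral and Σ piece lengths equals the centerline length.
* Junction pieces span node ± 1 mm (default half-width); the junction's
  viscous drop is charged at the mother flow, and the flow reduction takes
  effect at the piece's distal boundary in both solvers.
* Flow conservation at junctions is exact by construction (`Q_sb = Q_mov −
  Q_mb`).
* Flagged (unsegmentable) frames interpolate linearly in area; vessels need
  at least two valid frames, reference fits at least ten samples.
* Determinism: every stochastic component takes an integer seed; the full
  pipeline embeds a SHA-256 configuration hash in each artifact and
  reruns are byte-identical.

## Known limitations

* Steady flow only: no pulsatility, wave propagation, or microvascular
  models (CFR/IMR out of scope by design).
* The fixed-inflow boundary condition overestimates trans-lesion pressure
  drop for severe lesions (no flow limitation); see the redraw rule above.
* `D_mb` at a junction is accepted as labeled input; estimating it from the
  ostium geometry within the frames is not modelled.
* The 3-D lumen is reduced to `A(s)` immediately; eccentric lumina with
  equal area are indistinguishable to the solver.
* Finet's flow rule and the rest→hyperemia factor are stated
  interpretations/parameters, not measurements.
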