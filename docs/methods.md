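# Methods

`cardionuc` quantifies how sarcomere contraction couples into nuclear
deformation in adult cardiomyocytes, how the perinuclear microtubule (MT)
cage shapes and damages the nucleus, and how these effects interact with
nuclear-lamina stiffness. Because no raw microscopy accompanies the
quantitative claims the package reproduces, every analysis stage is driven
by a synthetic-data generator with analytic ground truth; the generators are
first-class, tested code, and their defaults encode the published group
phenotypes.

## Contraction traces

A paced cell is modelled as a sarcomere-strain waveform sampled at
`sampling_rate` (default 90 frames/s) under `pacing_frequency` (default
1 Hz). Per cycle the strain is a raised-cosine shortening of duration
`contraction_time_constant` (default 1/6 s, chosen so the peak lands on a
sample at 90 fps) followed by an exponential re-lengthening with time
constant `relaxation_time_constant` (default 0.2 s), shifted so that the
waveform returns exactly to zero at the cycle end. The functional form of
the waveform is not published; this shape is a stand-in calibrated to the
printed peak values.

The nuclear response is a first-order linear lag of sarcomere strain,

    tau_n * d(eps_n)/dt = g * eps_s(t) - eps_n(t),

integrated at periodic steady state with an exact exponential recursion on a
fine grid (the periodic initial condition follows in closed form from the
linearity of the lag). A single time constant `nuclear_time_constant`
(default 0.12 s) captures both amplitude dampening and diastolic
hysteresis. Nuclear width moves opposite to length through `width_gain`
(default −0.35); whether width shares the length kinetics is not published,
so it is slaved to the length strain. A viscoelastic standard-solid nuclear
model was considered and rejected as an extra parameter the available
anchors cannot constrain.

The gain `g` is calibrated per preset so that the *measured* peak nuclear
compression — computed by the pipeline's own strain estimator on a
noiseless cycle — equals the preset target within 0.005 percentage points;
a target requiring `g > 1.5` raises a calibration error. Preset targets:
WT rat −11.4 % sarcomere / −6.6 % nuclear; acute LINC disruption
(AdV DN-KASH) −12.0 / −6.2 (stronger contraction, weaker transfer);
colchicine −12.5 / −7.2 with faster sarcomere relaxation (0.13 s) and a
slower nuclear lag (0.20 s), producing the diastolic-hysteresis increase;
WT mouse −10.5 / −6.0. The N195K mutant preset sets its nuclear target to
1.30 × the WT-mouse target with identical kinetics, so the integrated
nuclear strain ratio is exactly 1.30 by construction — the published
anchor is the ~30 % headline, not the kinetic decomposition. Measurement
noise is additive Gaussian per frame (default 0.01 um in cohort scripts).

## Strain-coupling assay

Strains are percent changes relative to the diastolic baseline. The default
baseline is the mean over a 55-ms quiescent window that ends 44 ms before
the onset crossing of the smoothed provisional strain (computed against the
series median, which is robust to frame noise); a first-sample rule is
available. The window is defined in time, not frames, so estimates agree
across sampling rates; the fixed backoff keeps it unbiased when noise
defeats amplitude-based quiet-point detection.

Cycles are segmented per pacing period: onset is the first crossing of
|eps_s| above 0.5 % (configurable), peak systole is the in-period extremum,
relaxation end is the return below threshold. The coupling path resamples
each cycle's contraction and relaxation limbs onto 200 uniform
sarcomere-strain grid points before averaging, so path integrals depend
only on the traversed geometry; limbs are extended a few frames past the
threshold crossings so the path starts and ends at the quiescent level
regardless of sampling rate.

Systolic dampening is |∫ (eps_n − eps_s) d eps_s| over the contraction
limb: zero iff coupling is lossless along the identity line. Diastolic
dampening uses a unit-slope reference line anchored at the end-systolic
point (default); a chord-through-origin reference is available because the
published phrasing is ambiguous. Both are trapezoid integrals in units of
%² — the published axes carry no units, so only orderings and ratios are
treated as anchored. Integrated nuclear strain is ∫|eps_n| dt over one
pacing period (signed-versus-absolute is not published; absolute is used),
with the last sampled frame extended to close the period. Compressive
strain is negative internally; peak metrics are reported as positive
magnitudes. Group summaries are mean ± SE with n; no hypothesis tests.

## Synthetic images and morphometrics

Fields are rendered at 0.1 um/pixel (2-D mid-plane, the default analysis
geometry) or 0.25 um/voxel (3-D): an ellipsoidal chromatin nucleus
(default semi-axes 6.2 × 2.8 um), a lamina shell, a tubulin channel with
uniform cytoplasm plus a perinuclear ring of width 1 um whose level is
`enrichment_factor` × cytoplasm (optionally boosted toward the tips), and
punctate foci. An optional chromatin protrusion is a disk (default radius
0.8 um) straddling one tip, with a partial lamina gap. Images are blurred
by an isotropic Gaussian PSF (default sigma 0.1 um) and degraded with
Gaussian (default) or Poisson-Gaussian noise; ground truth (shape,
protrusion outside-ellipse area by fine quadrature, enrichment, foci) is
recorded before blur and noise. The generator emulates geometry, intensity
ratios and counting statistics — not photophysics: no spectral
bleed-through, drift, uneven illumination, depth attenuation, or
non-elliptical nuclear shapes. Passing tests therefore demonstrate that the
estimators are correct and unbiased on their stated geometry, not that they
are robust to every real-microscopy artifact.

Segmentation is Otsu thresholding → largest connected component → hole
fill, with a guard that rejects fields whose foreground/background
separation is below 2.2 image SDs (an Otsu split of pure noise). Nuclear
length/width are 4·sqrt(eigenvalue) of the mask's second central moments
(exact for a uniform ellipse and rotation-invariant to <2 %); area is the
pixel sum.

Perinuclear enrichment is the mean tubulin intensity in the band within
1 um outside the nuclear boundary over the mean in the 2–4 um cytoplasmic
band (both configurable; the published cytoplasmic region is shown only
pictorially). A 0.2-um guard trims both edges of the perinuclear band so
PSF blur across the band edges does not bias the ratio. Tip/side sectors
split the band at ±30° around the major axis (the published split names
tips versus sides without an angle). The 1-um band width is published for
rupture-reporter foci and reused for tubulin for consistency. Note the
ground-truth `enrichment_factor` is the ring's base level: with a tip
boost the measured overall ratio exceeds it by design.

Protrusion scoring operationalizes published criteria that live in
unavailable supplementary material: the mask is fitted by its moment
ellipse, robustly re-fitted five times with outside pixels excluded so a
protrusion cannot inflate the fit; residual mask pixels outside the
ellipse, in the tip sectors, whose component reaches a radial clearance of
3 % beyond the boundary (rejecting pixelation slivers) and totals
≥ 1 um², flag a protrusion. On the synthetic cohorts this detector makes
essentially no classification errors, so cohort prevalence reflects the
planted Bernoulli rate; prevalences are reported with seeded percentile
bootstrap CIs (2000 resamples).

Foci detection thresholds at background mean + 3 SD (sigma-clipped),
filters components to 0.05–5 um², and keeps those whose centroid lies in
the admissible zone: nucleus ∪ 1-um perinuclear ring (rupture-reporter
mode) or nuclear interior (DNA-damage mode). Reported per-focus areas are
measured at half maximum above background so they track the physical focus
rather than the detection threshold.

## Cohorts and biphasic regression

`generate_cohort` draws enrichment uniformly over a range (default
1.0–3.5) and sets aspect ratio on a continuous two-segment line —
defaults: deflection at enrichment 1.9, lower slope −2.1 AR per enrichment
unit, flat upper segment, AR 2.5 at the deflection — plus Gaussian noise
(default SD 0.15, a visual match to the published scatter).

`loess_fit` is a tricube-weighted local linear smoother (degree 1, default
span 0.75) with a pointwise ±1 SE band from the local weighted-regression
variance (implemented directly; the available lowess routines return no
band). `piecewise_linear_fit` grid-searches 200 candidate breakpoints over
the interior 5th–95th quantiles of x, minimizing the SSE of the continuous
two-segment least-squares fit (basis 1, min(x−b,0), max(x−b,0)); ties
break toward the smaller breakpoint and the winner is polished by a
bounded 1-D search between its grid neighbours, so noiseless two-segment
data is recovered essentially exactly. Per-segment slope SEs and p-values
use segment-local residual variance and t-statistics; the upper segment is
called flat when p > 0.05. The published fit names no span, search method
or slope test; these are documented choices, and no breakpoint-inference
correction (e.g. Davies) is applied. A free-intercept variant sits behind
`continuity=False`.

## Axisymmetric mechanics model

The resting cardiomyocyte is a cylinder (radius 9 um, half-length 16 um)
containing a round nucleus (radius 3.5 um; nucleoplasm plus a 0.15-um
NE+lamina layer) surrounded by an ellipsoidal MT cage (outer semi-axes
4.2 × 6.8 um — thin at the equator, thick at the poles, encoding the
tip-enriched cage). Exploiting symmetry, the quarter plane is meshed with
a body-fitted ray-layer triangulation: the lamina is resolved with two
element layers, region labels are exact, and the cytoplasm grades
geometrically outward. Elements are linear (P1) triangles with one-point
axisymmetric integration — sufficient for the band and ordering checks
targeted here and far simpler than a quadratic formulation.

All regions are compressible neo-Hookean (finite-strain kinematics are
needed because aspect-ratio changes are large in the cage-disrupted
scenarios). Total Cauchy stress adds an active part: the myofibril
contractility tensor ρ in the cytoplasm and an isotropic compressive
stress −σ_MT·I in the cage. ρ starts isotropic with magnitude ρ0 and, after
the quasi-static ramp of (ρ0, σ_MT) from zero (the two loads ramp
proportionally; the published schedule is graphical only), a single
polarization update concentrates it along the local
maximum-principal-stress direction n:

    rho = 3 rho0 (lambda n⊗n + (1−lambda)/2 (I − n⊗n)),  lambda = 0.5,

which preserves the average motor density tr(ρ)/3. The published text
states the outcome (fibers aligned with maximum principal stress), not the
law; an iterative fixed-point variant was considered and left out because
the single update already aligns the fibers. Boundary conditions: u_z = 0
on both cell ends (myocardial constraint; cell length is conserved to
<1e-8), u_r = 0 on the axis, lateral surface traction-free. Newton
iterations use a central-difference consistent tangent assembled per
element, a backtracking line search, convergence to a relative residual of
1e-8, and automatic load-step halving.

The constitutive parameters of the published model live in unavailable
supplementary material, so the defaults here are calibrated stand-ins
chosen so the model's probe stresses land inside the printed ranges:
cytoplasm 7 kPa (ν 0.3), nucleoplasm 0.3 kPa (ν 0.48, nearly
incompressible), cage 8 kPa (ν 0.4), lamina 40 kPa (ν 0.3) with the
mutant-lamin scenarios at the printed 10 kPa; ρ0 = 2.2 kPa and
σ_MT = 3.8 kPa. LINC-complex disruption scales both the cage stress and
stiffness to 0.3× (the cage is lost together with the motors that load
it); MT enrichment maps linearly onto (σ_MT, cage modulus) relative to the
wild-type enrichment 2.2. Under these defaults the wild-type solve yields
myofibril diastolic tension ≈ 2.8 kPa at the cage short tip (printed range
2–3), cage axial compression ≈ 1.0 / 1.4 kPa at the nucleus long/short
tips (printed range 1–1.8), aspect-ratio ordering WT < csDN-KASH <
mutant+csDN-KASH with the mutant-alone within 15 % of WT, monotonically
decreasing aspect ratio in σ_MT, and a biphasic (decreasing-then-flat)
aspect-ratio-versus-enrichment sweep whose plateau is the rigid-cage
limit.

Probes are element-averaged axial Cauchy stresses over ±20° sectors: the
near-cage cytoplasm band (1.5 um) at the cage short/long tips for
myofibril tension, and the cage region at the nucleus tips for MT
compression. The maximum-principal-stress location on the lamina is
reported as a normalized arc coordinate s (0 = equator, 1 = tip), and tip
instability is operationalized as s crossing 0.8, with the critical σ_MT
interpolated between bracketing load levels (the published account
describes the instability qualitatively).

### Known limitations

Two published properties do not emerge from this reduced model and are
deliberately left as failing acceptance checks rather than being fitted:

* *Minimum myofibril tension at the cage long tip.* On the symmetry axis
  the traction vector is continuous across the cytoplasm–cage interface,
  so the cytoplasm element touching a cage pole under ~1 kPa axial
  compression cannot simultaneously carry 2–3 kPa tension; the probe reads
  ≈ 0. Reproducing the printed value would require measuring away from the
  interface or a multi-field (fiber + matrix) cytoplasm.
* *Lamina-gated tip instability.* The stress-location shift to the tips
  does occur under supraphysiological cage stress, and reducing the cage
  afterwards returns the maximum principal stress to the nuclear middle
  while the nucleus elongates (the rescue sequence passes). But the shift
  is not gated by lamina stiffness: a buckling-type bifurcation of the
  thin compressed shell requires a shell formulation with imperfection
  seeding, which a two-layer P1 continuum lamina cannot produce.

Also: the model is diastolic only (no active twitch), axisymmetric, and
its absolute aspect-ratio changes (~1.04–1.10 across scenarios) are much
smaller than the measured ones — with a single-field continuum cytoplasm,
parameter sets that reproduce the printed stress bands produce small
nuclear deformations; orderings and monotonicities, not magnitudes, are
the anchored outputs. Scenario volume changes are reported as directions
only.

## Reproducibility and problem sizes

Every stochastic step flows through one explicit seeded generator; child
seeds derive from a global seed by SHA-256, so pipeline stages are
independently reproducible and reruns are bit-identical. Default problem
sizes — 90-frame cycles, 50 cohorts × 300 points for the regression
recovery, 500 images for prevalence, ~950-element meshes with 20 ramp
steps — were chosen so each analysis is statistically decisive at
desk scale; the full demonstration pipeline completes in a few minutes on
one CPU.
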