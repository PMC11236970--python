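# Methods

`cortexshape` measures how an actomyosin cortex deforms the membrane of
a giant unilamellar vesicle (GUV), from two-channel (membrane + actin)
timelapse images, and interprets the measurements with a closed-form
mechanical model. This note records the models, the estimators, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## Geometry and conventions

Images are 2D mid-plane (contour work) or bottom-surface (texture work)
frames. Physical coordinates are x = column × pixel size, y = row ×
pixel size, in micrometres; angles are measured counter-clockwise from
+x in that frame. Default calibration: 0.0938 µm/pixel, 6 s frame
interval, 2 min observation window (21 frames), matching the
spinning-disk configuration the pipeline is designed for. Contours are
closed polylines of N = 360 vertices (1° angular resolution), enough to
keep the polygonal error on the circularity of a circle below 10⁻⁴
while averaging pixel noise.

## Contour extraction and shape metrics

The membrane channel shows a thin bright ring. The extractor casts 360
rays from a center estimate (Otsu threshold → largest component →
centroid), samples the radial intensity profile with cubic
interpolation at 0.25 px steps, and locates the ridge per ray by
log-parabolic interpolation of the three samples around the maximum —
exact for a Gaussian-blurred thin shell, which is what a sub-resolution
membrane is. The center is re-estimated from the traced contour and the
trace repeated (3 iterations, with a shrinking radial search window).
On noise-free renderings the residual vertex error is ~0.02 px; at
shot-noise levels typical of spinning-disk data it stays below 0.1 px
RMS.

From the closed polygon: area A (shoelace), perimeter L (segment sum),
circularity C = 4πA/L², membrane strain ε_memb = 1 − C. The radial
profile R(θ) about the vertex centroid r_c is obtained by ray casting
with periodic linear interpolation; the deformation amplitude is
u(θ) = R(θ) − ⟨R⟩_θ. Contours must be star-shaped about r_c; a
backtracking polar angle raises an error naming the offending angle
rather than silently switching parameterizations.

Actin polarity P_act = |r_act − r_c| / R, where r_act is the
actin-intensity-weighted mean of the membrane vertex positions and the
intensity at each vertex is averaged over a band of ±3 px along the
local normal (the cortex is sub-resolution thick; a narrow band avoids
volume signal). R is the mean radius of the first frame, fixed per
liposome, so P_act of later frames is normalized by the initial size.
Cohort summaries exclude liposomes with mean radius below 17.5 µm
(configurable), where bending costs suppress deformation.

## Deformation spectra, deformation size, curvature

The angular power spectrum uses the convention power(q) =
c_q|FFT(u)(q)|²/N (one-sided, c_q = 2 except at q = 0 and Nyquist), so
Parseval reads Σ_q power = N·var(u) and a pure mode a·cos(qθ) carries
a²N/2. Only the scaling of the spectrum is physically meaningful; the
normalization is fixed so it is testable.

The scaling exponent α is the least-squares slope of log-power against
log-q. Modes q = 0 (area) and q = 1 (translation) are excluded by
construction. The default fit band is q ∈ [2, 10]: beyond the modes
that carry deformation signal, contour-extraction noise produces a
flat power floor which would bias a fit "over all q" toward small α,
so the band covers the resolvable range (configurable). α ≈ 4 indicates
an elasticity/bending-dominated response, α ≈ 2 a tension-dominated
one, following the fluctuation form ⟨|u(q)|²⟩ ∼ (κq⁴ + γq²)⁻¹. That
form is also fitted directly, in log space with κ, γ ≥ 0,
parameterized as A/(wq⁴ + (1−w)q²) with w ∈ [0, 1] to remove the
amplitude degeneracy; fitted κ and γ are reported in arbitrary units
unless the spectrum is calibrated, and one-parameter fits are flagged
when w pins at a bound.

The characteristic deformation size θ_c is computed per frame as the
first zero crossing (sign change + linear interpolation) of the
circular autocorrelation of u(θ), then minimized over frames; the
frame attaining the minimum is t′. The ACF is normalized by its lag-0
value — this does not move the zero crossing. Against a brute-force
ACF on a 10× finer grid the zero agrees to well under 0.5°.

Local curvature comes from an algebraic Pratt circle fit through each
vertex and its ±5th neighbors (≈±5° at N = 360; the spacing is
configurable and the three-point circle is the circumcircle, so the
fit is exact on circles). The sign follows the local turning
direction; collinear triplets are flagged with curvature 0. The total
turning Σκ ds closes to 2π within 1% on all generated simple contours.

## PIV, compressive strain, cortical flow

Displacements between consecutive frames are measured by multi-pass
normalized cross-correlation: a cascade of (interrogation, search)
windows — (100, 200), (60, 120), (48, 96) px by default, with a
48 px final window for volume contraction and 16–32 px for cortical
flow — where each pass's field seeds the next pass's search offsets.
Sub-pixel peaks use 3-point Gaussian interpolation. A vector is kept
only if the correlation peak is ≥ 0.6, its prominence over the
secondary peak is ≥ 0.20, and it passes a normalized-median outlier
test (threshold 5) against its 8 neighbors; these thresholds mirror
the nominal correlation/noise/threshold settings of common PIV tools,
without claiming bit-level equivalence to any particular plugin.
Featureless windows yield invalid vectors, never zeros.

The divergence is computed by central differences on the PIV grid
after filling invalid nodes from their nearest neighbors (the fill is
used for differencing only; reported vectors keep their validity
flags) and a 1-node Gaussian pre-smoothing of the components —
standard strain post-processing that is exact for linear fields and
suppresses node-to-node correlation noise (set `smooth_nodes=0` for
raw differences). Compressive strain accumulates only the negative
part of the divergence, area-averaged over the liposome interior:

ε(t) = −Σ_{t′≤t} [∫ min(∇·u, 0) dA / ∫ dA],

which keeps ε monotone under expansion noise. Cumulative displacement
is per-pair displacement summed on the fixed Eulerian grid: frame-to-
frame motions are at most a few pixels, so trajectory integration is
unnecessary. Cortical flow speed averages |u| over vectors within a
band (≥ one grid spacing) inside the membrane contour, converted to
µm/min, with tangential/normal components taken relative to the local
radial direction. The band average sits at a slightly smaller radius
than the contour, so a rigid rotation reads ~5% below its rim speed —
within the reported uncertainty of the measurement this emulates.

## Nematic order of the cortex texture

The director field is the eigenvector of the smaller structure-tensor
eigenvalue (along ridges) of the Gaussian-smoothed gradient field
(default smoothing 2 px); coherence is the normalized eigenvalue
anisotropy, and directors are kept where coherence ≥ 0.2. The local
order parameter at a lattice of reference points is S = mean over the
4 axial neighbors of cos 2(θ_neighbor − θ_ref); ⟨S⟩ averages S over
the analysis mask. Two choices deserve comment:

- **Reference axis.** S is computed relative to the reference point's
  own director, so it measures local alignment and is invariant under
  rotating the image — an aligned-vs-disordered readout cannot depend
  on the arbitrary camera frame.
- **Neighbor spacing.** The lattice steps 8× the smoothing length
  (16 px at default settings). Neighbors closer than the texture's own
  orientation correlation length lie on the same filament and read
  S ≈ 1 for any architecture; the spacing must step past that length
  for ⟨S⟩ to discriminate ordered from disordered cortices. On the
  dense filament textures of the benchmark (filament length ~30 px,
  ~10⁴ filaments per 1024² frame), ⟨S⟩ tracks the generating
  distribution's ⟨cos 2(θ − axis)⟩ within ±0.05 over the relevant
  range (≈0.3–0.5) and a 50/50 aligned/random mixture reads ⟨S⟩ ≈ 0.5.
  For sparse fields of statistically independent directors the same
  statistic instead estimates the squared resultant — local relative
  alignment and global order only coincide when directors blend across
  overlapping structures, as they do on dense cortical textures.
  Whether to average over all pixels or only high-coherence pixels is
  exposed via the coherence cutoff and mask arguments.

## Cortex thickness

The cortex (h ≈ 0.3 µm) is below the optical resolution
(σ_PSF ≈ 0.119 µm, calibrated by symmetric 2D Gaussian fits to ≥3
isolated, unsaturated sub-resolution beads), so h is inferred from the
distance Δ between the membrane-fluorescence peak and the actin peak
along the inward normal. For a cortex slab of plateau intensity I_S
spanning [0, h] inward of the membrane, over interior I_V and exterior
I_out, Gaussian blur puts the actin peak at h/2 + δ with
δ = (σ²/h)·ln r, r = (I_out − I_S)/(I_V − I_S), so h = 2(Δ − δ).
Because δ depends on h, the pair is a quadratic,
h² − 2Δh + 2σ² ln r = 0, solved exactly; the physical root
h = Δ + √(Δ² − 2σ² ln r) is the branch with h → 2Δ as σ → 0. A
negative discriminant means the measured profile is inconsistent with
the two-peak model and raises an error rather than returning a
clipped value.

Profiles are sampled along inward normals at 120 rays (cubic
interpolation, 0.25 px steps), aligned per-ray at the membrane peak,
and averaged; plateaus come from the profile tails, and peak positions
and the peak height from least-squares parabolas over ±3 samples (log
scale for the Gaussian membrane ridge), balancing sub-sample accuracy
against shot noise. One correction goes beyond the closed form: when
h ≲ 2σ the blurred actin peak does not reach the plateau I_S, and
using the observed peak height in r biases h low (by >10% at
h = 0.15 µm). `estimate_thickness` therefore iterates h and I_S to
joint consistency with the observed peak height and position, using
the analytic expression for the blurred peak height; the closed-form
`thickness_from_profile` remains available and unmodified. With the
correction, round-trip recovery through rendered images is within 10%
for h ∈ [0.15, 0.6] µm at shot-noise SNR ≈ 20.

## Mechanical model

All scaling relations are evaluated with prefactor exactly 1 and the
outputs labelled order-of-magnitude estimates; everything is computed
in SI units. Deformation of depth δ over a correlation length ξ_c
(default ξ_c = R·θ_c with θ_c in radians) costs

- F_bend ∼ E h³ δ² / ξ_c²,
- F_stretch ∼ E h ξ_c² δ² / (R²(1 + ξ_c²/R²)),
- F_memb ∼ γ_m ξ_c² δ / R,

with W_contract ∼ F_bend + F_stretch + F_memb at the onset of
deformation. Whether the geometric factor (1 + ξ_c²/R²) divides or
multiplies F_stretch is ambiguous as the scaling is usually written;
both readings are implemented behind a flag (`divide` is the default,
the form as written) and they differ by that factor squared. Because
of this prefactor uncertainty the tension worked example accepts an
externally supplied stretching energy (`F_stretch_override_J`).

Cortex tension γ_c = h·σ_act is computed by two routes: from the work,
σ_act = W R/(h ξ_c² δ) (γ_c is then independent of h at fixed W); and
from the force balance on a flowing cortex, σ_act = f_fric = ζ v_act
with ζ = η_m N_link/(4πR²). On typical inputs (R = 20 µm, h = 0.29 µm,
δ = 1.1 µm, θ_c = 28°, E = 4×10³ Pa, γ_m = 10⁻⁷ N/m, η_m = 10⁻⁵
Pa·s·m, N_link = 5×10⁵ — consistent with 25 nM of membrane-bound
nucleator in an R = 20 µm vesicle — v_act = 13.3 µm/min) the two
routes land within a factor of four, the agreement expected of
unit-prefactor scaling.

The binding-site budget checks that His-tagged nucleators fit on the
membrane: N_tot = 4πR²/a₀ lipid head groups (a₀ = 0.55 nm²), a Ni-NTA
anchor fraction (default 0.10), N_prot = c·(4/3)πR³·N_A encapsulated
copies, and a steric ceiling 4R²/r_prot² (r ≈ 4 nm for the formin
construct, ≈2 nm for the VCA fragment). An ATP helper does the
depletion arithmetic (5 mM − 4 µM/min × 10 min ≈ 4.96 mM), confirming
ATP is not limiting on the experiment's timescale.

## Synthetic benchmark: what it emulates, and what it does not

Every estimator is validated against scenes with recorded ground
truth:

- **Contours** r(θ) = R + Σ_q Re[a_q e^{iqθ}], q = 2…n_modes, with
  independent complex amplitudes of per-quadrature variance
  ∝ (κq⁴ + γq²)⁻¹; q = 0 and 1 are excluded (area/translation — the
  analysis measures shape, not size or position). Self-intersecting
  draws are rejected and resampled, with a bounded retry count. The
  amplitude scale is set by the RMS of u (default 2% of R).
- **Rendering**: the membrane is a thin shell blurred with the
  Gaussian PSF; the actin channel is the cortex slab model above,
  blurred analytically along the contour normal (exact for gently
  curved shells; the signed depth is computed radially, so rendering
  assumes star-shaped contours). Noise is Poisson shot noise at a gain
  giving SNR ≈ 20 at the cortex peak plus Gaussian read noise,
  mimicking spinning-disk data. The renderer refuses intensity
  orderings where the cortex is not the brightest radial feature.
  Default surface-to-volume contrast I_S/I_V ≈ 2.9, inside the
  1.8–7.7 range observed for well-localized cortices; configurable.
- **Speckle pairs** advected by analytic flows (translation, radial
  contraction u_r = −kr, rigid swirl) whose displacement and
  divergence truths are exact.
- **Filament textures** with von Mises orientations of prescribed
  ⟨cos 2θ⟩ and anti-aliased segments; the realized per-draw order is
  recorded as truth.
- **Polarized cortices**: the azimuthal intensity profile (cosine,
  step, or von Mises family) is solved by bisection on the actual
  polygon sum so the constructed polarity matches the target to 10⁻⁶;
  unreachable targets report the family's maximum.
- **Bead fields** of isolated Gaussian spots (≥6σ separation) for PSF
  calibration.
- **Cohorts**: three architecture presets (branched "arp23": low
  polarity 0.10, small strain 0.006, bending-regime spectrum,
  low-mode ellipsoidal deformation; linear "mdia1": polarity 0.20,
  strain 0.005, tension-regime spectrum, high-mode deformation,
  smallest θ_c; "mixed": polarity 0.24, strain 0.018, bending regime,
  intermediate modes). A deterministic mode ramp is scaled by
  bisection so the final-frame ε_memb equals the preset target, with
  per-frame fluctuation modes superposed; truth tables are computed
  from the true contours, so pipeline recovery is scored against
  geometry, not against another image analysis.

What passing these tests shows: the estimators are unbiased (or biased
within the stated tolerances) on images whose formation model is known
and matches the assumptions — Gaussian PSF, two-channel alignment,
star-shaped mid-plane contours, a single liposome per frame. What they
do not show: robustness to out-of-focus light and z-dependent blur,
chromatic misalignment, photobleaching, membrane tubulation or
non-star-shaped blebs, neighboring liposomes and debris, or motion
blur during exposure. The cohort presets reproduce the *relative*
signatures of the three architectures (rank order of ε_memb^max,
P_act^max, α, θ_c), not any particular biological effect size. The
spectral α of the ramped cohort scenes is a signature, not a
calibrated recovery: calibrated α recovery (within ±0.5) is
demonstrated separately on pure fluctuation ensembles rendered and
re-extracted through the full imaging path.

## Problem sizes and determinism

Unit and acceptance tests run on scaled-down scenes chosen to keep the
full suite around a minute on one CPU: cohort scenes at 0.25 µm/pixel
and 9–11 frames (the estimators are resolution-calibrated, so
sub-pixel behavior is exercised at full resolution in the dedicated
thickness/contour tests at 0.0938 µm/pixel), spectra averaged over
20 frames as in the standard protocol, ensemble spectrum checks over
500–600 draws, and order-parameter textures of 10⁴ filaments at 1024².
`scripts/acceptance.py` re-runs every headline measurement from
scratch with all randomness derived from a single `--seed`. Pipeline
runs are deterministic given the config seed, and outputs carry a hash
of the configuration.

## Known limitations

- The thickness estimator assumes the actin peak lies inside the
  membrane peak; the sign convention is asserted, and violations
  (e.g. external actin) surface as errors rather than being flipped.
- The PIV quality filter approximates, but is not bit-identical to,
  the window/correlation semantics of specific GUI PIV tools.
- κ and γ from the fluctuation fit are relative (arbitrary units);
  the pipeline uses the spectrum only for regime classification via
  α, not for calibrated moduli.
- ⟨S⟩ depends on the neighbor lattice spacing relative to the
  texture correlation length; the default is calibrated for dense
  cortical textures and should be revisited for sparse filament
  fields (see the nematic-order section).
- Mid-plane 2D analysis only; no 3D surface reconstruction, no
  deconvolution (the thickness estimator is designed for PSF-blurred
  data), and no dense optical-flow alternative to PIV.
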