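# Methods

`echowss` measures two-dimensional blood velocity fields, vessel-wall
position and wall shear stress (WSS) from high-frame-rate
contrast-enhanced B-mode-like image sequences, and ships a moving-wall
pulsatile-flow speckle phantom whose analytic flow solution provides an
exact validation oracle. This note records the models, the numerical
choices, and what the phantom does and does not emulate.

## The phantom

### Flow model

Flow in a straight tube of time-varying radius R(t) is either

* **Poiseuille** (quasi-steady): axial velocity
  `u(r,t) = 2 v̄(t) (1 − (r/R)²)`, wall shear rate `4 v̄/R`;
* **Womersley** (default): the prescribed spatial-mean velocity
  waveform `v̄(t)` is decomposed into its first 12 Fourier harmonics;
  each harmonic k carries the classic Bessel-function profile
  `1 − J₀(β_k ρ)/J₀(β_k)` with `β_k = i^{3/2} α_k` and Womersley number
  `α_k = R̄ √(k ω ρ_b/μ_b)` evaluated at the time-mean radius. The
  profile is scaled quasi-statically to the instantaneous radius
  (ρ = r/R(t)), and the harmonic amplitudes are normalized so that the
  cross-sectional mean reproduces the truncated waveform exactly. The
  wall shear rate is the closed-form derivative
  `γ(t) = 4V₀/R − (2/R) Re Σ A_k β_k J₁(β_k)/J₀(β_k) e^{ikωt}`.

A linear-in-r radial velocity `(r/R) dR/dt` carries the wall motion,
so the no-slip condition holds on the moving wall. Because the
scatterers are advected by this same field, the generated images come
with a velocity and WSS oracle that is exact by construction — the
point of replacing a discretized CFD solution. Radial advection uses
the exact integral of the linear field (`d ← d·R(t+Δt)/R(t)`), so a
lumen scatterer can never cross the wall; a crossing raises, it is
never clamped.

Default conditions: diameter pulsating 2.6→2.8 mm over a 1/3 s cardiac
cycle; spatial-mean velocity waveform peaking at ≈0.26 m/s with a brief
early-diastolic reversal (constructed from periodic von-Mises bumps,
band-limited to the 12 harmonics the Womersley model uses); blood
density 1044.0 kg/m³ and viscosity 4.043 mPa·s; 15° beam-to-flow
angle; 200 µm three-layer wall; PRF 4500 Hz with 3 interleaved
angles → 1500 compounded fps.

### Scatterers and rendering

Point scatterers populate the lumen, three equal 67 µm wall layers
(intima, media, adventitia) and the surrounding tissue at 10 per
resolution cell (FWHM area of the point-spread function). Amplitudes
follow a two-component model: magnitude drawn as mean ± SD per
compartment (tissue 2.5 ± 0.01, intima 0 ± 1, media 2.5 ± 0.01,
adventitia 0 ± 0.01, microbubble 1.4 ± 0.01) with a random sign.
The media keeps a fixed sign (`specular_layers`): its scatterers sum
coherently, producing the bright specular wall reflection that the
directional peak fit targets — with random signs the wall would be no
brighter than tissue speckle of equal mean. Wall layers translate
radially with the wall; tissue follows with a 1/|d| decaying radial
displacement.

Advection runs at the transmission PRF (4500 Hz); each substep renders
one low-resolution frame into the corresponding angle stack, so
consecutive frames of one angle stack are 1/1500 s apart exactly as in
interleaved plane-wave imaging, and the compounded stack is the
per-frame mean. Rendering splats amplitudes bilinearly onto the pixel
grid and convolves with a separable Gaussian PSF (σ axial 2 px,
lateral 3 px at 30 µm/px); the image is a linear, RF-like signed
field — speckle arises from amplitude interference, and envelope
detection (`|·|`) happens downstream where intensities are needed.
Additive Gaussian noise (σ = 0.02) models the electronic floor.
Scatterers washing out of the vessel ends are dropped; a 20 × 20 grid
of image sub-regions (5% × 5% rectangles) is topped back up to the
density target by uniform insertion inside the lumen part of each
rectangle, never removing scatterers.

What the phantom does **not** emulate: nonlinear/harmonic microbubble
response, RF-domain beamforming, attenuation and shadowing,
out-of-plane motion, frequency-dependent viscoelastic wall mechanics,
fully developed-speckle statistics of a physical aperture. Passing the
in-silico validation therefore demonstrates the correctness of the
measurement chain under ideal 2-D imaging assumptions, not in-vivo
performance.

## Clutter filtering

The Casorati matrix (pixels × frames) of each angle stack is
factorized by an economy SVD (via the frames × frames Gram matrix when
pixels ≫ frames; identical to working precision and an order of
magnitude faster). The blood band's low cut uses the spatial
similarity of the |U| vectors: tissue components share the anatomy of
the dominant component, so the cut is placed at the first component
whose Pearson correlation with |U₀| falls below 0.5. An adjacent-pair
similarity statistic was tried first and proved fragile when tissue
collapses into a single dominant component (the transition dip then
has no second tissue component to contrast with). A candidate band
holding less than 1e−8 of the stack energy means the stack is static
and raises. The high cut defaults to keeping the entire post-low-cut
spectrum: truncating at a cumulative-energy fraction (e.g. 90%)
discards genuine broadband blood speckle and temporally mixes frames —
on the phantom it degraded the lumen-mean velocity waveform error
roughly tenfold. The parameter remains exposed for noisy in-vivo data.

## PIV

Multipass, window-deforming, ensemble-averaged normalized
cross-correlation. Windows start at 32 × 32 px and halve three times
(32→16→8→4, 50% overlap): with the deforming predictor the 4 px final
pass is stable and places the first velocity estimate two pixels from
the wall, which matters for near-wall shear (below). Correlation
planes are zero-mean normalized and computed by zero-padded FFT; the
raw linear correlation is divided by the per-lag overlap count —
without this the triangular overlap weighting drags both the integer
peak and the sub-pixel fit toward zero lag (a ~0.1–0.3 px bias at
2–3 px displacements) — and the search is restricted to ±w/2 where the
overlap-corrected estimate is stable. Sub-pixel refinement is a
three-point Gaussian fit per axis with a parabolic fallback for
non-positive neighbours. With interleaved plane-wave stacks, the
planes of all angle pairs at one time instant are averaged before peak
detection (incoherent ensemble correlation). Outliers are rejected by
the normalized median test on 3 × 3 neighbourhoods (threshold 2.0,
noise floor 0.1 px) and replaced by the median of valid neighbours.
Displacements convert to m/s via pixel spacing over the pair interval.

## POD denoising

The velocity-field series (concatenated u, v state vectors) is
denoised by proper orthogonal decomposition of the *fluctuations about
the temporal mean*, keeping modes up to 95% of the fluctuation energy.
The convention matters: the mean flow carries almost all raw energy,
so a raw-energy fraction of 0.95 collapses the series to a single mode
and smears the waveform in time. Invalid vectors are filled by local
3 × 3 medians before the decomposition and re-masked afterwards.

## Wall tracking

1. **Augmentation.** The compounded stack is SVD-split into tissue and
   blood; the envelope of each is moving-window averaged (10 frames),
   normalized by its maximum, and subtracted (tissue − blood): lumen
   strongly negative, wall strongly positive. A numerically empty
   component is zeroed rather than normalized, so a static stack does
   not amplify noise.
2. **Narrow-band level set.** A region-based (two-region
   mean-separation) active contour with curvature regularization
   (weight 0.2) evolves only the ±2 px band of the signed distance
   function, which is clipped outside the band and rebuilt every 5
   iterations; convergence is judged per re-init block (< 0.5% of band
   pixels changing sign). The first frame gets 500 iterations from a
   programmatic initialization (Otsu threshold of the blood envelope);
   subsequent frames start from the previous mask with a 40-iteration
   budget.
3. **Directional peak fitting.** Boundary normals sample the tissue
   envelope outward; the wall point is the sub-pixel half-maximum
   crossing on the lumen side of the first intensity peak with
   topographic prominence ≥ 5% of the image maximum. Prominence-based
   detection rejects the low bumps that residual lumen signal leaves
   near the wall; the 5% default separates the media reflection from
   bright tissue speckle merging behind it (larger thresholds let the
   merged blob capture the crossing and bias the wall outward).
   Points without a qualifying peak fall back to the mask contour,
   flagged.
4. **Parameterization and smoothing.** Near-horizontal walls are
   re-expressed as y(x) on a 1 px lateral grid (median per bin —
   contour folds from mask notches collapse here), outliers beyond
   2 px from a 9-point running median are clipped to it, and the
   border is Savitzky–Golay smoothed (window 21, order 2) with θ
   recomputed from the smoothed tangents. Boundaries are classified
   upper/lower (split at the extremal along-vessel points of each
   lumen component's contour) and primary/secondary (largest lumen
   first); classification uses only mask geometry, so intensity
   rescaling cannot change labels.

The diameter waveform is tracked independently by 1-D
cross-correlation of axial envelope profiles at 10 stations along the
wall (windows placed on median-filtered per-column wall rows, station
median). Two alignment modes exist: successive-frame shift
accumulation, and alignment of every frame against the first frame.
At 1500 fps the per-frame wall motion (~0.004 px) is far below the
correlator's resolution and the successive mode's random error
integrates into a drift comparable to the pulsation itself, so the
validation experiment uses the reference mode, which recovers the
0.2 mm peak-to-peak pulsation to within about ±7% across seeds on the
full-size phantom.

Segmentation is scored by the Dice coefficient of the refined
(boundary-filled) masks over the evaluated lateral extent and by the
one-sided mean absolute distance between walls (ground truth → 
measurement), as `MADW = (1/n)Σ|d(i, M, GT)|`.

## Wall shear stress

WSS is `τ_w = μ_b ε̇′₁₂` with the unhalved strain-rate convention
`ε̇_ij = ∂u_i/∂x_j + ∂u_j/∂x_i` rotated into the wall frame by
`a = [[cos θ, sin θ], [−sin θ, cos θ]]` (`ε̇′_mn = a_mi a_nj ε̇_ij`).
In the pipeline the tangential wall gradient is estimated from
velocity profiles sampled along the inward wall normal at the velocity
grid's own pitch (finer sampling adds no information), projected onto
the wall tangent — the profile equivalent of the tensor rotation,
since ∂u_n/∂s vanishes on the wall. Each profile is filtered by a
third-order Savitzky–Golay filter of relative length n/D = 0.4 and
differentiated at the wall from the two closest valid points with the
no-slip zero anchored at the wall point — the exact wall derivative of
the through-origin quadratic, which reproduces a parabolic profile
exactly. Two guard steps next to the wall are skipped: image
velocities within roughly one axial PSF width of the boundary are
biased toward the faster lumen side, because the speckle contributing
to those pixels comes one-sidedly from deeper fluid. (An anchored
three-point cubic that tracks boundary-layer curvature is available
via ``fit_points``; it buys systolic amplitude in pulsatile flow at
the price of amplifying the near-wall bias, and the two-point form was
kept as the default on the steady-flow oracle.) Per-point shear is
median filtered along the border (width 5). TAWSS and OSI use
trapezoidal time integrals; OSI is clipped to [0, 0.5] and defined as
0 where TAWSS is 0. τ_w is signed positive for forward flow on both
boundaries (derivative along the inward normal), so the two walls
average constructively.

Known limitation: the first velocity estimate sits half a final
interrogation window from the wall, so the estimated shear is a
secant through fluid at finite depth. In pulsatile flow the true wall
shear phase-leads that fluid (Stokes-layer physics), which appears as
a small residual lag of the measured WSS waveform — visible in the
in-silico validation as the main remaining error term, and intrinsic
to the achievable spatial resolution rather than to the estimator.

## Validation experiment

The in-silico validation generates the default phantom (one cycle,
500 frames at 128 × 512 px), runs SVD → PIV → POD → wall → WSS on the
rendered images only, and scores against the oracle: the lumen-mean
velocity waveform and both-boundary mean WSS waveform (mean absolute
deviation normalized by the reference maximum, in %), point-by-point
velocity magnitude (normalized by the global true maximum) and
direction errors (vectors above 5% of peak true speed), DSC and MADW.
Velocity comparisons use PIV nodes inside the instantaneous true lumen
eroded by half the final interrogation window, with truth and
measurement averaged over the same support. `scripts/acceptance.py`
reruns the whole experiment from a seed. Problem size (one cycle,
desk-scale image) keeps the full run in minutes on one CPU.
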