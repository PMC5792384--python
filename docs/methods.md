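# Methods

`petmoco` is a desk-scale, fully synthetic simulation of MR-based motion
correction for dynamic cardiac PET parametric imaging.  Everything — the
anatomy, the tracer kinetics, the PET and MR acquisitions, the motion, and
the ground truth against which results are judged — is generated inside the
package, so every quantity the evaluation reports can be traced to a
configuration block and a master seed.

## The experiment

Four reconstructions of the same dynamic acquisition are compared:

- **ST** (static): motionless, noise-free reference.
- **GA** (gated): only events from the reference motion phase
  (end-diastole / end-exhalation) are reconstructed — motion-frozen but
  count-starved (10% of events for cardiac-only gating, 4% for dual
  cardiac-respiratory gating).
- **NMC** (no motion correction): every phase reconstructed and summed
  without warping — all events, motion-blurred.
- **MC** (motion-corrected): each phase reconstructed with its own
  (MR-derived) attenuation map, warped to the reference phase through the
  MR-estimated motion field, then summed — all events, motion-frozen up to
  registration error.

Voxelwise K1 maps are fitted to each series; per-ROI K1 mean and standard
deviation across Poisson noise realizations quantify bias (vs ST and vs
the generating truth) and noise, with the expectation that MC approaches
GA's accuracy at NMC's noise level.

## Phantom and motion

A single coronal 128x128 plane at 3-mm isotropic pixels (3-mm slice)
holds a circular LV myocardial ring (inner/outer radii 12/24 mm) with LV
and RV blood pools, two lungs, a liver and a soft-tissue body ellipse. A
non-transmural perfusion defect occupies a 4-mm-thick radial band over a
12-mm arc at the mid-anterolateral wall.  The plane is coronal so the
dominant superior-inferior respiratory translation stays in-plane.

Ground-truth motion is analytic and invertible: a radial contraction about
the LV centre with a Gaussian spatial envelope (scale 40 mm, peak
fractional contraction 0.10) for the cardiac cycle, and a rigid
superior-inferior translation of the torso (peak 10 mm) for respiration.
Both are modulated by raised-cosine cyclic weights that vanish at the
reference phase.  Cycles are divided evenly into phases: 10 cardiac phases
for the cardiac-only pattern (CM), 5 cardiac x 5 respiratory for the
combined pattern (CRM).  The amplitudes are free parameters of the
generator; the defaults sit in the typical clinical range (free-breathing
SI heart excursion ~10 mm, systolic radial contraction ~10%), and results
are functions of them.

Tissue assignments: healthy myocardium K1 = 0.80 mL·min⁻¹·mL⁻¹,
k2 = 0.17 min⁻¹; defect K1 = 0.36, k2 = 0.21; PD/T1/T2 = 0.67/830 ms/62 ms
(myocardium) and 0.77/1080 ms/82 ms (defect); 511-keV attenuation
0.0096 mm⁻¹ for water-like tissue, 0.3x for lung.  Blood pools carry the
arterial input function directly.  Lung/liver/soft-tissue kinetics are
package defaults (low uptake), overridable per config.

## Kinetics

The arterial input function is a Feng-type parametric bolus
Cp(t) = (A1·t − A2 − A3)e^(−λ1 t) + A2 e^(−λ2 t) + A3 e^(−λ3 t) with
defaults (4000, 20, 21, 2.0, 0.12, 0.01 min⁻¹): peak ≈ 760 near 0.5 min,
slowly decaying tail ≈ 40, a bolus-to-tail ratio (~19x) typical of
first-pass perfusion tracers.  The ratio matters beyond realism: the
last-frame count calibration (below) fixes the late-frame statistics, and
the bolus amplitude decides how many counts the short early frames
receive.  Tissue curves follow the one-tissue compartment model
Ct = K1·Cp ⊗ e^(−k2 t), evaluated on a 0.1-s grid with trapezoid
quadrature via the exponential-kernel identity (exact to the quadrature
order, O(n) per curve).  The dynamic schedule is 8x5 s, 4x10 s, 2x20 s,
1x40 s, 1x2 min, 1x4 min (17 frames, 520 s).

The measured myocardial frame value mixes ventricular spillover:
C_PET(t_m) = f_LV·C_LV + f_RV·C_RV + (1 − f_LV − f_RV)·frame-avg(Ct).

### Fitting

Voxelwise unweighted least squares over (K1, k2, f_LV, f_RV).  Two
numerical choices matter at the count levels simulated:

- **Initialization** is a profiled grid search: at fixed k2 the model is
  linear in (f_LV, f_RV, (1−f)·K1), so an ordinary least-squares solve on
  a 40-point k2 grid locates the global basin before a bounded
  trust-region polish (`scipy.optimize.least_squares`, ftol 1e-8).
- **Bounds** are symmetric: K1 ∈ [−5, 5], f ∈ [−2, 2], k2 ∈ [0, 2] min⁻¹
  (a washout cap ~10x the physiological value), with a soft penalty
  keeping f_LV + f_RV ≤ 1.  Negative estimates are retained: at low SNR
  the unweighted estimator spreads symmetrically about the truth, and
  clipping at zero would bias every ROI mean upward — gating, which is
  exactly ST in expectation, would have appeared 80–150% biased.  Physical
  generation parameters remain non-negative (`require_physical`).

Noise-free round trips recover the generating parameters to machine
precision; the 1% acceptance tolerance is comfortably met.

## PET forward model and reconstruction

Mean sinogram = A·G·P·x per (frame, phase): P is a 4.5-mm-FWHM Gaussian
PSF in image space; G is an exact Siddon ray tracer over a 2D
parallel-beam geometry (180 angles over [0, π), 128 radial bins of 3 mm,
matching the pixel grid and covering the body's ±165 mm support without
truncation); A is the diagonal of per-bin attenuation factors
exp(−∫μ dl) computed with the same Siddon traversal.  Scatter and randoms
are not modeled; MR thermal noise is not modeled.

Counts are scaled once so the noise-free total in the last (4-min) frame,
summed over all phases and bins, is 50,000 for the 3-mm slice; each of
the N phases receives 1/N of every frame's duration.  Poisson noise is
drawn bin-wise; realization r of master seed s uses the dedicated stream
`SeedSequence([s, r])`, so realizations are independent and reproducible.

Reconstruction is attenuation-precorrected FBP: band-limited Ram-Lak
kernel (Kak-Slaney discretisation, quantitative to ~0.1% on a uniform
disk) with a Hann apodization window at the 3-mm Nyquist, linear-interp
sparse backprojection.  The window/bin choice matches the reconstruction
bandwidth to the 50k-count statistics; an unwindowed or finely-binned
ramp passes noise far above the pixel Nyquist and pushes the voxelwise
fits into a bound-saturated regime in which the GA/NMC/MC comparison
degenerates.  GA images are divided by the gated count fraction so all
four series share concentration units; a 4-pixel LV blood-pool ROI in the
noise-free ST series reproduces the framed input function to <0.5%
(image-derived input function check).

For speed the forward model exploits linearity: per phase, the warped
indicator map of each tissue label is blurred and projected once, and
every frame's mean sinogram is a per-label linear combination; FBP of
sinogram stacks is one sparse matrix product.

## MR simulation and motion estimation

Per-phase MR magnitude images use the analytic steady-state spoiled-GRE
signal S = PD·sinα·(1−E1)/(1−cosα·E1)·e^(−TE/T2), E1 = e^(−TR/T1), with
TR = 9.56 ms, TE = 2.4 ms, α = 46°, T2 standing in for T2* (no
off-resonance model), optionally passed through a fully-sampled k-space
round trip.  Images are normalized to a study-wide maximum so
registration sees consistent intensities.

Motion fields are estimated with multi-resolution Demons registration
(SimpleITK `DemonsRegistrationFilter`; pyramid shrink factors 4/2/1 with
100/50/25 iterations and field smoothing of 1.5 pixels per level).  Each
phase is registered twice — phase→reference and reference→phase — rather
than inverting one field.  Against the ground-truth deformation the
estimated fields have sub-pixel mean endpoint error; the reference
attenuation map transported to a phase by the measured field matches the
true phase map to <10% NRMSE over the attenuating support.

## Evaluation

The myocardium mask thresholds the noise-free last-frame ST image at 50%
of max (largest connected component).  Four nominal-0.18-mL ROIs (7
pixels at 3-mm isotropic) sit at septal, anterior, defect-centre and
inferior-lateral mid-wall anchors; healthy ROIs use only pixels at least
one erosion step from the wall edge, and the defect ROI centres on the
defect band.  Per ROI and method: the ROI-mean K1 per realization, then
mean and (N−1)-normalized SD across N = 25 realizations; bias of method M
is (K̄₁ᴹ − K̄₁ˢᵀ)/K̄₁ˢᵀ, "true bias" divides by the generating K1, and the
noise reduction of MC vs GA is |σ_MC − σ_GA|/σ_GA.

## What the synthetic study shows — and what it does not

With the default CRM conditions (25 phases, 10-mm respiration, 10%
contraction, 50k calibrated counts, 25 realizations) the package
reproduces the directional findings: MC lowers |K1 bias| vs ST relative
to NMC in at least 3 of 4 ROIs; σ_GA exceeds σ_MC with reductions of
~70–90% in every ROI; MC and NMC image noise agree within a few percent
(same event count; measured per-frame over a uniform tissue region); and
the healthy-defect K1 contrast is larger for MC than NMC.

Known limitations, mostly consequences of desk scale:

- **2D geometry.** A real scanner's 3D acquisition pools axial
  information, so its per-voxel SNR at the same per-slice count level is
  several times higher.  Two consequences here: the gated series' noisy
  voxel fits are variance-dominated (its K1 means carry little
  information even though the noise-free GA series equals ST exactly, as
  the simulation verifies directly), and K1-level σ for NMC exceeds MC's
  in blurred-wall ROIs because motion-mixed TACs add model-misfit
  variance on top of count noise.
- The phantom's tissues are piecewise-constant with analytic motion; real
  data add heterogeneous uptake, through-plane motion, scatter/randoms
  and attenuation-map segmentation error, none of which are modeled.
- Registration quality is bounded by the synthetic MR contrast; tissues
  with identical relaxation parameters (the two blood pools) provide no
  internal gradient for Demons, exactly as uniform myocardium limits
  untagged GRE in practice.
- The sub-pixel cardiac contraction (~1.6 mm at the wall) is near the
  resolution limit, so MC's gain over NMC for cardiac-only motion is
  small — blur and its correction are dominated by respiration.

Passing tests therefore demonstrate internal consistency of the
simulation chain and the directional superiority of MR-based motion
correction under these synthetic conditions, not clinical performance.

## Problem sizes

Defaults were chosen so a full CRM study (128x128 grid, 17 frames, 25
phases, 25 realizations, 48 registrations, ~5,000 voxel fits) completes
in a few minutes on one CPU; the oracle suites (Siddon vs dense
sampling, convolution vs closed forms, FBP round trips, known-shift
registration) run in seconds.
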