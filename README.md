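# petmoco

Desk-scale simulation of **MR-based motion correction for dynamic cardiac
PET parametric imaging**.

Cardiac contraction and breathing blur dynamic PET of the heart and bias
the kinetic parameters fitted from it — above all K1, the
one-tissue-compartment uptake rate that tracks myocardial blood flow.
Gating freezes motion but discards most events; simultaneous PET-MR
offers a better deal: estimate dense motion fields from MR images
acquired per motion phase, reconstruct each phase with all of its events,
warp every phase into a reference anatomy and sum.  `petmoco` builds the
entire experiment synthetically — a moving 2D thorax phantom, dynamic PET
acquisition with attenuation, resolution blur and Poisson noise, spoiled
gradient-echo MR images per phase, Demons motion estimation, filtered
back-projection, voxelwise kinetic fitting — so the bias and variance of
static (ST), gated (GA), uncorrected (NMC) and motion-corrected (MC)
K1 maps can be measured against a known ground truth.

It is a library for people who study PET motion correction or kinetic
parameter estimation and want a controlled, fully reproducible sandbox.

## The model in brief

Tissue activity follows the one-tissue compartment model

    Ct(t) = K1 · Cp(t) ⊗ e^(−k2 t),

driven by a Feng-type arterial input function Cp.  A measured myocardial
frame value adds ventricular spillover:

    C_PET(t_m) = f_LV·C_LV(t_m) + f_RV·C_RV(t_m)
                 + (1 − f_LV − f_RV) · (1/Δt_m) ∫ Ct dτ.

Noise-free mean sinograms follow the linear forward model **ȳ = A G P x**
(P: 4.5-mm Gaussian PSF, G: Siddon ray-traced parallel-beam projector,
A: attenuation factors), scaled so the 4-min frame holds 50,000 true
counts, with bin-wise Poisson noise per realization.  Voxelwise
unweighted least squares over (K1, k2, f_LV, f_RV) produces parametric
maps; per-ROI K1 mean/SD across realizations yield the bias and
noise-reduction figures.  See `docs/methods.md` for the full account.

## Worked example

`examples/` holds one short script per capability; `02_kinetics_round_trip.py`:

```text
$ python examples/02_kinetics_round_trip.py
AIF: peak 761 at t=0.51 min, tail 26 (arbitrary concentration units)
framed myocardial TAC (first 5 frames): [  3.5  22.   53.7  93.9 138.9]
recovered K1=0.8000 (truth 0.80), k2=0.1700 (truth 0.17), converged=True
K1 tracks myocardial blood flow; k2 is the washout rate.
```

The framed values are the frame-averaged tissue concentrations the
scanner would measure in the first five 5-s frames; the fitter recovers
the generating uptake and washout rates exactly from noise-free data.

`examples/05_full_study.py` runs the reduced end-to-end study and prints
the per-ROI K1 table: GA shows near-ST means with an order-of-magnitude
larger SD (4% of events), NMC shows motion-inflated bias at full-count
noise, and MC sits near ST's bias at NMC's noise level, with a larger
healthy-vs-defect contrast than NMC.

Other examples: `01_build_phantom.py` (anatomy, tissue table, motion
amplitudes), `03_project_and_reconstruct.py` (forward model, calibration
and FBP quantitation), `04_motion_estimation.py` (MR simulation and
Demons field accuracy against ground truth).

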