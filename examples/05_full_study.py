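"""Run a reduced end-to-end motion-correction study and print the ROI table.

Executes the whole chain (phantom -> dynamic PET + MR simulation -> Demons
motion estimation -> ST/GA/NMC/MC reconstruction -> voxelwise K1 fitting ->
ROI statistics) for the combined cardiac-respiratory motion pattern with a
small number of noise realizations, then prints K1 bias and noise per ROI.

Takes a few minutes; pass an output directory to also write NIfTI maps,
the CSV table and the reproducibility manifest.
"""

import sys

from petmoco import StudyConfig, run_study

outdir = sys.argv[1] if len(sys.argv) > 1 else None
cfg = StudyConfig(motion="CRM", n_realizations=5, seed=1)
res = run_study(cfg, outdir=outdir)

print(f"motion: {cfg.motion} ({res.phase_spec.total_phases} phases), "
      f"{cfg.n_realizations} noise realizations, scale {res.scale:.3e}")
cols = ["study", "roi", "K1_mean", "K1_sd", "bias_vs_ST", "true_bias"]
print(res.roi_table[cols].round(3).to_string(index=False))

print("\nDefect contrast (healthy minus defect ROI K1):")
for mode in ("NMC", "MC"):
    print(f"  {mode}: {res.defect_contrast(mode):.3f}")
print("Reading: GA freezes motion but keeps only 4% of events (huge K1 sd); "
      "NMC keeps all events but blurs; MC warps each phase to the reference "
      "before summing, cutting the bias at the NMC noise level.  ROI "
      "statistics at 5 realizations are rough; the acceptance study uses 25.")
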