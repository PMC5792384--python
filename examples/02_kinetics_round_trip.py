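"""Generate a myocardial time-activity curve and fit it back.

Evaluates the default arterial input function, builds the healthy-
myocardium tissue curve from the one-tissue compartment model, frame-
averages it over the 17-frame dynamic schedule, and recovers (K1, k2)
with the unweighted least-squares fitter.  Noise-free recovery is exact
to well below 1%.
"""

import numpy as np

from petmoco import (FrameSchedule, InputFunction, KineticParams,
                     eval_input_function, fit_voxel, frame_average, tissue_tac)

aif = InputFunction()
schedule = FrameSchedule()

t = np.arange(5201) * (0.1 / 60.0)  # 0.1-s grid over 520 s, in minutes
cp = eval_input_function(aif, t)
print(f"AIF: peak {cp.max():.0f} at t={t[np.argmax(cp)]:.2f} min, "
      f"tail {cp[-1]:.0f} (arbitrary concentration units)")

truth = KineticParams(K1=0.80, k2=0.17)
tt, ct = tissue_tac(truth, aif)
target = frame_average(tt, ct, schedule)
blood = frame_average(t, cp, schedule)
print("framed myocardial TAC (first 5 frames):", np.round(target[:5], 1))

fit = fit_voxel(target, aif, blood, blood, schedule,
                init=KineticParams(0.5, 0.2), fit_spillover=False)
print(f"recovered K1={fit.params.K1:.4f} (truth 0.80), "
      f"k2={fit.params.k2:.4f} (truth 0.17), converged={fit.converged}")
print("K1 tracks myocardial blood flow; k2 is the washout rate.")
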