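"""Distance bands from the CSF surfaces and cohort quartile cutpoints.

WM and deep-grey voxels are banded by distance from the ventricles (10
equal-width bands per subject, the innermost and outermost dropped against
partial-volume contamination, survivors renumbered 1..8).  The cortical
ribbon gets 2 depth bands by a median split from the outer CSF surface.
"""

import numpy as np

from lesionmtr import TrialConfig, build_bands, build_unit_tables, simulate_trial

trial = simulate_trial(TrialConfig(n_patients=8), seed=11)
bands = build_bands(trial.atlas)

wm_counts = np.bincount(bands.wm_dgm_band[bands.wm_dgm_band > 0], minlength=9)[1:]
print("WM/DGM voxels per band (1 = nearest ventricles):", wm_counts.tolist())
cgm_counts = np.bincount(bands.cgm_band[bands.cgm_band > 0], minlength=3)[1:]
print("CGM voxels per band (1 = inner, 2 = outer):", cgm_counts.tolist())

tables = build_unit_tables(trial)
for (level, variable, tissue), sd in tables["strata"].items():
    cuts = ", ".join(f"{c:.2f}" for c in sd.cutpoints)
    print(f"{level:7s} {variable:12s} {tissue:9s} {sd.scheme:12s} cuts: {cuts}")
print("Cutpoints are cohort-level, fitted on baseline only; pure WM uses "
      "quartiles, the sparser GM lesion classes a median split.")
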