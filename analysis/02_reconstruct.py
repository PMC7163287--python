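#!/usr/bin/env python
"""IDEAL fat-water reconstruction of the simulated acquisition.

Reads the phantom acquisition written by 01_simulate_phantom.py, runs the
full reconstruction (field map, joint R2*, water/fat, PDFF), and reports
voxelwise recovery errors against the simulation truth in
results/recon_recovery.csv.

Expected outcome: sub-percent PDFF error in the median at SNR 30 and no
fat-water swap voxels.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from adipoquant import reconstruct
from adipoquant import io as aqio

PHANTOM = Path("scratch/phantom")
RESULTS = Path("results")

series = aqio.load_echo_series(PHANTOM / "echoes.nii.gz", PHANTOM / "meta.json")
truth = aqio.load_maps(PHANTOM / "truth_maps")

maps = reconstruct(series)
aqio.save_maps(maps, PHANTOM / "recon_maps", series.voxel_size)

fg = (truth.pdff > 0) & maps.valid
pdff_err = np.abs(maps.pdff - truth.pdff)[fg]
psi_err = np.abs(maps.fieldmap - truth.fieldmap)[fg]
r2_rel = np.abs(maps.r2star - truth.r2star)[fg] / np.maximum(truth.r2star[fg], 1)

rows = [
    {"quantity": "pdff_abs_error", "median": np.median(pdff_err),
     "p95": np.percentile(pdff_err, 95), "max": pdff_err.max()},
    {"quantity": "fieldmap_abs_error_hz", "median": np.median(psi_err),
     "p95": np.percentile(psi_err, 95), "max": psi_err.max()},
    {"quantity": "r2star_rel_error", "median": np.median(r2_rel),
     "p95": np.percentile(r2_rel, 95), "max": r2_rel.max()},
    {"quantity": "fat_water_swaps", "median": 0.0, "p95": 0.0,
     "max": float((pdff_err > 0.5).sum())},
]
df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "recon_recovery.csv", index=False, float_format="%.6g")
print(df.to_string(index=False))
print(f"\n{int(fg.sum())} foreground voxels; maps in {PHANTOM/'recon_maps'}")
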