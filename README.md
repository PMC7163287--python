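# adipoquant

Quantification of adipose tissue depots around the osteoporotic hip from
chemical-shift-encoded (CSE) MRI, with the cohort statistics used to relate
depot fat content to clinical fracture risk.

Increased bone-marrow fat is associated with lower bone mineral density and
higher fracture risk. CSE-MRI measures fat non-invasively: a multi-echo
gradient-echo acquisition encodes the fat-water chemical shift in the
inter-echo phase evolution, and inverting that signal model yields the
proton density fat fraction (PDFF) of every voxel. This package implements
the full analysis chain for a hip protocol (3 T, 128x128 matrix, 40 slices,
3 or 6 echoes at 2.1-5.9 ms) as a tested, reusable pipeline:

1. **Signal model** — eight-peak triglyceride fat spectrum; voxel signal
   `s(t) = (W + F·Σₚ aₚ e^{i2πfₚt}) · e^{i2πψt} · e^{−R2*t}`
   with water/fat amplitudes `W, F`, field-map off-resonance `ψ` (Hz) and
   shared decay rate `R2*` (1/s).
2. **IDEAL reconstruction** — coil-sensitivity-corrected combination, then
   per-voxel inversion of the model by variable projection: `W, F` are
   profiled out in closed form and `(ψ, R2*)` found by grid search, spatial
   smoothing (fat-water-swap defense) and alternating 1-D refinement.
   `PDFF = F/(F+W)`.
3. **Segmentation** — background mask from `F+W`, PDFF binarization at 50%,
   region-based active contours on the binarized map (C1) and its inverse
   (C2), mask algebra M1=C1, M2=C2, M3=¬M2, M4=M1∖M2, then depot thresholds
   (muscle < 50% in M2, marrow > 50% in M3, subcutaneous fat > 70% in M4)
   with 2-D connectivity cleanup, on 20 slices centered on the femoral head.
4. **Quantification** — per-depot mean PDFF, mean R2*, and volume ratio
   (mask voxels / analyzed voxels).
5. **Statistics** — FRAX stratification (<10 / 10-20 / >20), per-group
   demographic summaries, Kruskal-Wallis and heteroscedastic (Welch +
   Brown-Forsythe) ANOVAs, per-group Pearson matrices, and a bidirectional
   stepwise-AIC regression of FRAX on z-scored depot metrics and
   demographics with all two-way interactions
   (`Y = α + Σβⱼxⱼ + Σγⱼₖxⱼxₖ + ε`), 5-fold cross-validation and
   Bland-Altman diagnostics.

No imaging data are redistributed: a digital hip phantom (exact PDFF, R2*
and field-map truth; two marrow islands, a muscle compartment, a
subcutaneous fat ring) and a three-stratum cohort simulator (n = 42/52/34,
demographics matching the published per-group summaries) generate every
input, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from adipoquant import (PhantomSpec, make_phantom, reconstruct,
                        segment_depots, depot_metrics)

spec = PhantomSpec(shape=(64, 64, 8), snr=30.0, seed=1)   # 6 echoes, 3 T
truth_maps, truth_seg, series = make_phantom(spec)
maps = reconstruct(series)                 # W, F, PDFF, R2*, field map
seg = segment_depots(maps, slice_count=8)  # BMAT / MUS / SAT labels
for d, m in depot_metrics(maps, seg).items():
    print(f"{d}: PDFF {m.mean_pdff_pct:.1f}%  R2* {m.mean_r2star:.1f} 1/s  "
          f"VOL {m.vol_ratio:.3f}  ({m.voxel_count} voxels)")
err = np.abs(maps.pdff - truth_maps.pdff)[(truth_seg.labels > 0) & maps.valid]
print(f"median |PDFF error| vs truth: {np.median(err):.4f}")
```

prints

```
BMAT: PDFF 75.0%  R2* 98.8 1/s  VOL 0.061  (1984 voxels)
MUS: PDFF 10.2%  R2* 40.0 1/s  VOL 0.390  (12768 voxels)
SAT: PDFF 84.9%  R2* 60.2 1/s  VOL 0.211  (6915 voxels)
median |PDFF error| vs truth: 0.0113
```

i.e. at SNR 30 the reconstruction recovers the phantom's true depot fat
fractions (75 / 10 / 85 %) and decay rates (100 / 40 / 60 s⁻¹) to about a
percentage point, and the segmentation isolates the three depots. The
`adipoquant` command exposes the same stages as subcommands
(`simulate`, `recon`, `segment`, `quantify`, `stats`, `run`).

## Analysis scripts

`analysis/01_simulate_phantom.py` … `04_cohort_statistics.py` run the whole
study narrative on synthetic data — phantom acquisition, reconstruction
recovery, segmentation fidelity plus depot metrics, and the cohort
statistics (group comparisons, correlation matrices, stepwise interaction
model with cross-validation and Bland-Altman) — writing tables under
`results/` (large/binary intermediates under `scratch/`).

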