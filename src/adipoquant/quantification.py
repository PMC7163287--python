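"""Per-depot integration of PDFF and R2* and volume-ratio computation.

For each depot mask the mean PDFF and mean R2* are taken over valid voxels,
and the depot volume VOL is the ratio of mask voxels to the total voxel count
of the analyzed sub-volume (the selected slice slab, not the full stack).
T2* in ms is reported alongside as 1000/R2*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recon import ParametricMaps
from .segmentation import DEPOTS, DepotSegmentation


@dataclass
class DepotMetrics:
    depot: str
    mean_pdff: float      # fraction in [0, 1]
    mean_r2star: float    # 1/s
    vol_ratio: float      # mask voxels / analyzed voxels
    voxel_count: int

    @property
    def mean_pdff_pct(self) -> float:
        return 100.0 * self.mean_pdff

    @property
    def mean_t2star_ms(self) -> float:
        """T2* = 1000 / R2* (ms); inf for non-decaying tissue."""
        return 1000.0 / self.mean_r2star if self.mean_r2star > 0 else np.inf


def depot_metrics(
    maps: ParametricMaps, seg: DepotSegmentation
) -> dict[str, DepotMetrics]:
    """Integrate the parametric maps over each depot mask."""
    if maps.pdff.shape != seg.labels.shape:
        raise ValueError("maps and segmentation are not co-registered")
    if seg.slice_range is not None:
        lo, hi = seg.slice_range
        n_total = maps.pdff.shape[0] * maps.pdff.shape[1] * (hi - lo + 1)
    else:
        n_total = maps.pdff.size
    out = {}
    for depot in DEPOTS:
        mask = seg.mask(depot)
        count = int(mask.sum())
        sel = mask & maps.valid
        if sel.any():
            mean_pdff = float(maps.pdff[sel].mean())
            mean_r2 = float(maps.r2star[sel].mean())
        else:
            mean_pdff = float("nan")
            mean_r2 = float("nan")
        out[depot] = DepotMetrics(
            depot=depot,
            mean_pdff=mean_pdff,
            mean_r2star=mean_r2,
            vol_ratio=count / n_total,
            voxel_count=count,
        )
    return out


def metrics_to_frame(subject_id: str, metrics: dict[str, DepotMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-depot frame for a subject."""
    rows = [
        {
            "subject_id": subject_id,
            "depot": m.depot,
            "mean_pdff_pct": m.mean_pdff_pct,
            "mean_r2star": m.mean_r2star,
            "vol_ratio": m.vol_ratio,
            "voxel_count": m.voxel_count,
        }
        for m in metrics.values()
    ]
    return pd.DataFrame(rows)
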