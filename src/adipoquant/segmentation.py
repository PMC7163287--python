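"""Three-depot segmentation of PDFF maps.

Workflow (per analyzed slab): a background mask from the total F+W signal
suppresses air; the PDFF map is binarized at 50% to split high-fat tissue
(subcutaneous fat and marrow) from low-fat tissue (muscle); region-based
active contours evolve the binarized map (C1) and its inverse (C2); mask
algebra M1 = C1, M2 = C2, M3 = not-M2 within foreground, M4 = M1 minus M2
follows; finally the depots are assigned by PDFF thresholds within the masks
(muscle PDFF < 50% in M2, bone-marrow adipose tissue PDFF > 50% in M3,
subcutaneous adipose tissue PDFF > 70% in M4) and cleaned up by 2-D
connectivity rules.

M3 and M4 both contain all high-fat tissue, so the thresholds alone cannot
split marrow from subcutaneous fat; connectivity disambiguates: high-fat
components touching the background boundary form the subcutaneous ring,
interior components (surrounded by muscle) are marrow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.segmentation import morphological_chan_vese

DEPOTS = ("BMAT", "MUS", "SAT")
LABEL_CODES = {"none": 0, "BMAT": 1, "MUS": 2, "SAT": 3}


@dataclass
class MaskSet:
    """Foreground, contour and algebraic masks, all co-registered booleans."""

    foreground: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    M3: np.ndarray
    M4: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.foreground, self.C1, self.C2,
                                    self.M1, self.M2, self.M3, self.M4)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")


@dataclass
class DepotSegmentation:
    """Final depot labels: 0 none, 1 BMAT, 2 MUS, 3 SAT."""

    labels: np.ndarray
    masks: dict = field(default_factory=dict)  # depot -> boolean map
    slice_range: tuple[int, int] | None = None  # inclusive

    def mask(self, depot: str) -> np.ndarray:
        return self.masks[depot]


def select_slices(n_slices: int, center_index: int, count: int = 20) -> tuple[int, int]:
    """Contiguous ``count``-slice range centered on ``center_index``.

    Ties of an even count break toward the lower index; the range is shifted
    to stay inside [0, n_slices).  Returns an inclusive (start, stop) pair.
    """
    if count > n_slices:
        raise ValueError(f"count {count} exceeds volume slices {n_slices}")
    if not (0 <= center_index < n_slices):
        raise ValueError("center index outside volume")
    # even count cannot center exactly: tie-break toward the lower index,
    # i.e. the center sits at position count//2 of the range
    start = center_index - count // 2
    start = int(np.clip(start, 0, n_slices - count))
    return start, start + count - 1


def background_mask(
    F: np.ndarray, W: np.ndarray, rel_threshold: float = 0.05
) -> np.ndarray:
    """Foreground where F+W exceeds rel_threshold x robust max; largest CC kept."""
    F = np.asarray(F, float)
    W = np.asarray(W, float)
    if F.shape != W.shape:
        raise ValueError("F and W must be co-registered")
    total = F + W
    robust_max = np.percentile(total, 99.0)
    fg = total > rel_threshold * robust_max
    if not fg.any():
        raise ValueError("signal-free input: all voxels fall below threshold")
    lab = measure.label(fg)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def binarize_pdff(
    pdff: np.ndarray, cut: float = 0.5, foreground: np.ndarray | None = None
) -> np.ndarray:
    """True where PDFF strictly exceeds ``cut`` (ties excluded), in foreground."""
    out = np.asarray(pdff, float) > cut
    if foreground is not None:
        out &= foreground
    return out


def evolve_contour(
    binary_init: np.ndarray,
    image: np.ndarray,
    iters: int = 100,
    smoothness: int = 1,
) -> np.ndarray:
    """Region-based (piecewise-constant) active-contour evolution.

    Morphological Chan-Vese, run per slice for 3-D input, seeded with the
    binary initialization.  ``smoothness`` is the integer number of
    curvature-smoothing passes per iteration (0-4).
    """
    init = np.asarray(binary_init, bool)
    if not init.any():
        raise ValueError("empty contour initialization")
    image = np.asarray(image, float)
    if image.shape != init.shape:
        raise ValueError("image and initialization must share a shape")
    smoothing = int(round(smoothness))
    if image.ndim == 2:
        return morphological_chan_vese(
            image, num_iter=iters, init_level_set=init, smoothing=smoothing
        ).astype(bool)
    out = np.zeros_like(init)
    for z in range(image.shape[2]):
        if init[:, :, z].any():
            out[:, :, z] = morphological_chan_vese(
                image[:, :, z], num_iter=iters,
                init_level_set=init[:, :, z], smoothing=smoothing,
            ).astype(bool)
    return out


def build_masks(C1: np.ndarray, C2: np.ndarray, foreground: np.ndarray) -> MaskSet:
    """Mask algebra: M1 = C1, M2 = C2, M3 = inverse of M2 (in foreground),
    M4 = M1 minus M2."""
    C1 = np.asarray(C1, bool)
    C2 = np.asarray(C2, bool)
    foreground = np.asarray(foreground, bool)
    if not (C1.shape == C2.shape == foreground.shape):
        raise ValueError("C1, C2 and foreground must share a shape")
    M1 = C1 & foreground
    M2 = C2 & foreground
    M3 = ~M2 & foreground
    M4 = M1 & ~M2
    return MaskSet(foreground=foreground, C1=C1, C2=C2, M1=M1, M2=M2, M3=M3, M4=M4)


def _filter_components_2d(
    mask: np.ndarray,
    foreground: np.ndarray,
    min_size: int,
    keep: str,
    max_components: int | None = None,
) -> np.ndarray:
    """Per-slice 8-connectivity cleanup.

    keep='interior': drop components 8-adjacent to background (marrow rule);
    keep='boundary': keep only components adjacent to background (subcutaneous
    ring); keep='any': size filter only.  ``max_components`` keeps the largest
    k surviving components per slice.
    """
    out = np.zeros_like(mask)
    struct = np.ones((3, 3), bool)
    for z in range(mask.shape[2] if mask.ndim == 3 else 1):
        sl = mask[:, :, z] if mask.ndim == 3 else mask
        fg = foreground[:, :, z] if mask.ndim == 3 else foreground
        if not sl.any():
            continue
        bg_dilated = ndimage.binary_dilation(~fg, structure=struct)
        lab, n = ndimage.label(sl, structure=struct)
        surviving = []
        for i in range(1, n + 1):
            comp = lab == i
            size = int(comp.sum())
            if size < min_size:
                continue
            touches = bool((comp & bg_dilated).any())
            if keep == "interior" and touches:
                continue
            if keep == "boundary" and not touches:
                continue
            surviving.append((size, comp))
        surviving.sort(key=lambda t: -t[0])
        if max_components is not None:
            surviving = surviving[:max_components]
        acc = np.zeros_like(sl)
        for _, comp in surviving:
            acc |= comp
        if mask.ndim == 3:
            out[:, :, z] = acc
        else:
            out = acc
    return out


def assign_depots(
    pdff: np.ndarray,
    masks: MaskSet,
    slice_range: tuple[int, int] | None = None,
    min_component: int = 20,
    bmat_cut: float = 0.5,
    mus_cut: float = 0.5,
    sat_cut: float = 0.7,
) -> DepotSegmentation:
    """Threshold-based depot assignment with connectivity enforcement.

    MUS = {PDFF < mus_cut} in M2; BMAT = {PDFF > bmat_cut} in M3;
    SAT = {PDFF > sat_cut} in M4 (strict inequalities, ties excluded).
    Connectivity: SAT keeps components touching the background boundary,
    BMAT keeps up to two interior components per slice (one per hip),
    MUS keeps all components above the minimum size.
    """
    pdff = np.asarray(pdff, float)
    fg = masks.foreground
    mus = (pdff < mus_cut) & masks.M2
    bmat = (pdff > bmat_cut) & masks.M3
    sat = (pdff > sat_cut) & masks.M4

    sat = _filter_components_2d(sat, fg, min_component, keep="boundary")
    bmat = _filter_components_2d(
        bmat & ~sat, fg, min_component, keep="interior", max_components=2
    )
    mus = _filter_components_2d(mus & ~sat & ~bmat, fg, min_component, keep="any")

    if slice_range is not None:
        lo, hi = slice_range
        keep = np.zeros_like(fg)
        keep[:, :, lo:hi + 1] = True
        mus &= keep
        bmat &= keep
        sat &= keep

    for name, m in (("BMAT", bmat), ("MUS", mus), ("SAT", sat)):
        if not m.any():
            warnings.warn(f"depot {name} is empty after filtering", stacklevel=2)

    labels = np.zeros(pdff.shape, dtype=np.uint8)
    labels[bmat] = LABEL_CODES["BMAT"]
    labels[mus] = LABEL_CODES["MUS"]
    labels[sat] = LABEL_CODES["SAT"]
    return DepotSegmentation(
        labels=labels,
        masks={"BMAT": bmat, "MUS": mus, "SAT": sat},
        slice_range=slice_range,
    )


def segment_depots(
    maps,
    center_slice: int | None = None,
    slice_count: int = 20,
    contour_iters: int = 50,
    smoothness: int = 1,
    rel_threshold: float = 0.05,
    min_component: int = 20,
) -> DepotSegmentation:
    """Full segmentation chain on a :class:`~adipoquant.recon.ParametricMaps`."""
    fg = background_mask(maps.F, maps.W, rel_threshold)
    pdff = maps.pdff
    n_slices = pdff.shape[2]
    if center_slice is None:
        center_slice = n_slices // 2
    sl = select_slices(n_slices, center_slice, min(slice_count, n_slices))
    c1_init = binarize_pdff(pdff, 0.5, fg)
    c2_init = fg & ~c1_init
    C1 = evolve_contour(c1_init, pdff, iters=contour_iters, smoothness=smoothness)
    C2 = evolve_contour(c2_init, pdff, iters=contour_iters, smoothness=smoothness)
    masks = build_masks(C1, C2, fg)
    return assign_depots(pdff, masks, slice_range=sl, min_component=min_component)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
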