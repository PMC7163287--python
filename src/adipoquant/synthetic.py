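"""Digital hip phantom and simulated cohorts.

The phantom is a stylized cross-section of the pelvis at the femoral heads:
an elliptical body whose outer annulus is subcutaneous fat (high PDFF), a
muscle compartment (low PDFF) filling the interior, and two circular marrow
regions (PDFF above the marrow threshold), constant through the slice stack.
Geometry is stylized rather than anatomical so the ground truth is exact;
the segmentation operators only need the real data's contrast and topology
(fat ring touching the background, marrow islands inside muscle).

Multi-echo data are produced by evaluating the chemical-shift forward model
on the truth maps at the protocol's echo times (2.1-5.9 ms, 3 T), with
independent complex Gaussian noise per voxel/echo/coil.  SNR is defined as
the mean foreground signal magnitude at the first echo over the noise SD.

Simulated cohorts mirror the reference study's three FRAX strata
(n = 42/52/34): demographics are drawn from truncated normals matching the
published per-group summaries, depot metrics from per-group normals with
configurable between-group effects (marrow and muscle PDFF increase with
fracture-risk stratum), and FRAX is generated from a planted
linear-plus-interaction model on the z-scored predictors, then clipped to
the group's stratum so labels and scores stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import tables
from .recon import EchoSeries, ParametricMaps
from .segmentation import LABEL_CODES, DepotSegmentation
from .signal_model import (
    EchoTimes,
    FatSpectrum,
    compute_pdff,
    default_echo_times,
    default_fat_spectrum,
    simulate_signal_maps,
)


@dataclass
class PhantomSpec:
    """Geometry, tissue truth and acquisition settings of the digital phantom."""

    shape: tuple[int, int, int] = (128, 128, 40)
    voxel_size: tuple[float, float, float] = (2.58, 2.58, 5.0)  # mm
    field_strength: float = 3.0
    n_echoes: int = 6
    snr: float | None = None          # None = noiseless
    n_coils: int = 1
    seed: int = 0
    # geometry, as fractions of the in-plane matrix
    body_radius: float = 0.46         # outer boundary of the fat ring
    sat_inner_radius: float = 0.38    # fat ring inner boundary
    marrow_radius: float = 0.10
    marrow_offset: float = 0.21       # lateral offset of each femoral head
    # tissue truth: PDFF fraction, R2* 1/s, signal amplitude
    pdff: dict = field(default_factory=lambda: {
        "BMAT": 0.75, "MUS": 0.10, "SAT": 0.85})
    r2star: dict = field(default_factory=lambda: {
        "BMAT": 100.0, "MUS": 40.0, "SAT": 60.0})
    amplitude: dict = field(default_factory=lambda: {
        "BMAT": 1.0, "MUS": 1.0, "SAT": 1.0})
    fieldmap_model: str = "ramp"      # constant | ramp | poly
    fieldmap_amplitude_hz: float = 30.0

    def __post_init__(self) -> None:
        if not (self.pdff["MUS"] < 0.5 < self.pdff["BMAT"]
                and self.pdff["SAT"] > 0.7):
            raise ValueError(
                "truth PDFFs must respect the depot thresholds "
                "(MUS < 0.5, BMAT > 0.5, SAT > 0.7)")
        if self.marrow_offset - self.marrow_radius <= 0:
            raise ValueError("marrow regions overlap the image center")
        if self.marrow_offset + self.marrow_radius >= self.sat_inner_radius:
            raise ValueError("marrow regions overlap the fat ring")

    def echo_times(self) -> EchoTimes:
        return default_echo_times(self.n_echoes)


def _phantom_labels(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    yy, xx = np.meshgrid(
        (np.arange(ny) - (ny - 1) / 2) / ny,
        (np.arange(nx) - (nx - 1) / 2) / nx,
    )
    r = np.hypot(xx, yy)
    body = r <= spec.body_radius
    sat = body & (r > spec.sat_inner_radius)
    mus = body & ~sat
    marrow = np.zeros_like(body)
    for sign in (-1, 1):
        marrow |= np.hypot(xx - sign * spec.marrow_offset, yy) <= spec.marrow_radius
    marrow &= mus
    mus = mus & ~marrow
    sl = np.zeros((nx, ny), dtype=np.uint8)
    sl[marrow] = LABEL_CODES["BMAT"]
    sl[mus] = LABEL_CODES["MUS"]
    sl[sat] = LABEL_CODES["SAT"]
    return np.repeat(sl[:, :, None], nz, axis=2)


def _truth_fieldmap(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    if spec.fieldmap_model == "constant":
        psi = np.full(spec.shape, spec.fieldmap_amplitude_hz)
    elif spec.fieldmap_model == "ramp":
        psi = spec.fieldmap_amplitude_hz * x * np.ones(spec.shape)
    elif spec.fieldmap_model == "poly":
        psi = spec.fieldmap_amplitude_hz * (x**2 + 0.5 * x * y - 0.3 * y**2) \
            * np.ones(spec.shape)
    else:
        raise ValueError(f"unknown fieldmap model {spec.fieldmap_model!r}")
    return psi


def _coil_sensitivities(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth complex sensitivities with unit root-sum-square per voxel."""
    nx, ny, nz = spec.shape
    sens = np.empty((nx, ny, nz, spec.n_coils), complex)
    for c in range(spec.n_coils):
        re = ndimage.gaussian_filter(rng.normal(size=(nx, ny)), nx / 6) + 1.0
        im = ndimage.gaussian_filter(rng.normal(size=(nx, ny)), nx / 6)
        sens[..., c] = (re + 1j * im)[:, :, None]
    rss = np.sqrt((np.abs(sens) ** 2).sum(-1, keepdims=True))
    return sens / rss


def make_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[ParametricMaps, DepotSegmentation, EchoSeries]:
    """Build truth maps and the simulated multi-echo acquisition."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _phantom_labels(spec)

    pdff = np.zeros(spec.shape)
    r2 = np.zeros(spec.shape)
    amp = np.zeros(spec.shape)
    for depot, code in (("BMAT", 1), ("MUS", 2), ("SAT", 3)):
        m = labels == code
        pdff[m] = spec.pdff[depot]
        r2[m] = spec.r2star[depot]
        amp[m] = spec.amplitude[depot]
    psi = np.where(labels > 0, _truth_fieldmap(spec), 0.0)
    W = amp * (1 - pdff)
    F = amp * pdff
    pdff_t, valid = compute_pdff(F, W)
    truth_maps = ParametricMaps(
        W=W, F=F, pdff=pdff_t, r2star=r2, fieldmap=psi, valid=valid,
        meta={"truth": True},
    )
    truth_seg = DepotSegmentation(
        labels=labels,
        masks={d: labels == c for d, c in
               (("BMAT", 1), ("MUS", 2), ("SAT", 3))},
        slice_range=(0, spec.shape[2] - 1),
    )

    tes = spec.echo_times()
    spectrum = default_fat_spectrum(spec.field_strength)
    signal = simulate_signal_maps(W, F, psi, r2, tes, spectrum)

    if spec.n_coils > 1:
        sens = _coil_sensitivities(spec, rng)
        signal = signal[..., None] * sens[:, :, :, None, :]

    if spec.snr is not None:
        fg = labels > 0
        ref = np.abs(simulate_signal_maps(W, F, psi, r2, tes, spectrum)[fg, 0]).mean()
        sd = ref / spec.snr
        noise = sd * (rng.standard_normal(signal.shape)
                      + 1j * rng.standard_normal(signal.shape))
        signal = signal + noise

    series = EchoSeries(
        data=signal, tes=tes, voxel_size=spec.voxel_size,
        field_strength=spec.field_strength,
    )
    return truth_maps, truth_seg, series


# ---------------------------------------------------------------------------
# cohort simulation

#: per-group depot-metric means; PDFF as fraction, R2* 1/s, VOL as ratio.
#: Marrow PDFF rises ~5 points and muscle PDFF ~9 points from LOW to HIGH,
#: matching the reported between-group contrasts; R2* and volumes carry no
#: group effect (none was observed).
DEFAULT_METRIC_MEANS = {
    "pdff_bmat": {"LOW": 0.72, "MOD": 0.74, "HIGH": 0.77},
    "pdff_mus": {"LOW": 0.100, "MOD": 0.096, "HIGH": 0.189},
    "pdff_sat": {"LOW": 0.85, "MOD": 0.85, "HIGH": 0.85},
    "r2star_bmat": {g: 100.0 for g in tables.GROUPS},
    "r2star_mus": {g: 40.0 for g in tables.GROUPS},
    "r2star_sat": {g: 60.0 for g in tables.GROUPS},
    "vol_bmat": {g: 0.030 for g in tables.GROUPS},
    "vol_mus": {g: 0.35 for g in tables.GROUPS},
    "vol_sat": {g: 0.12 for g in tables.GROUPS},
}

DEFAULT_METRIC_SDS = {
    "pdff_bmat": 0.06, "pdff_mus": 0.04, "pdff_sat": 0.04,
    "r2star_bmat": 15.0, "r2star_mus": 8.0, "r2star_sat": 10.0,
    "vol_bmat": 0.006, "vol_mus": 0.05, "vol_sat": 0.03,
}

#: planted coefficients of the FRAX generative model (on z-scored predictors)
DEFAULT_FRAX_COEFFICIENTS = {
    "pdff_bmat": 1.0,
    "pdff_mus": 0.8,
    "age": 0.6,
    "pdff_bmat:weight": 0.5,
}

FRAX_STRATA = {"LOW": (1.0, 9.99), "MOD": (10.0, 20.0), "HIGH": (20.01, 50.0)}


@dataclass
class CohortSpec:
    group_sizes: dict = field(
        default_factory=lambda: dict(tables.GROUP_SIZES))
    metric_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_METRIC_MEANS.items()})
    metric_sds: dict = field(default_factory=lambda: dict(DEFAULT_METRIC_SDS))
    frax_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_FRAX_COEFFICIENTS))
    frax_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.metric_sds.values()):
            raise ValueError("metric SDs must be non-negative")
        if self.frax_noise_sd < 0:
            raise ValueError("FRAX noise SD must be non-negative")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are printed min/max)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulated cohort table: demographics, depot metrics, FRAX, group."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    demo = tables.REFERENCE_DEMOGRAPHICS
    frames = []
    for group in tables.GROUPS:
        n = spec.group_sizes[group]
        rows = {"group": [group] * n}
        for var in ("height", "weight", "age"):
            c = demo[var][group]
            rows[var] = _truncnorm(rng, c["mean"], c["sd"], c["min"], c["max"], n)
        for metric, means in spec.metric_means.items():
            sd = spec.metric_sds[metric]
            x = rng.normal(means[group], sd, n)
            rows[metric] = np.clip(x, 1e-4, None)
        frames.append(pd.DataFrame(rows))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "id", [f"S{i:03d}" for i in range(len(cohort))])
    cohort["bmi"] = cohort["weight"] / cohort["height"] ** 2
    for col in ("pdff_bmat", "pdff_mus", "pdff_sat"):
        cohort[col] = cohort[col].clip(upper=1.0)

    # FRAX from the planted linear + interaction model on z-scored predictors,
    # around each group's published mean, clipped to the stratum
    z = {}
    for col in list(DEFAULT_METRIC_MEANS) + ["height", "weight", "age"]:
        x = cohort[col].to_numpy(float)
        sd = x.std(ddof=0)
        z[col] = (x - x.mean()) / sd if sd > 0 else x * 0.0
    signal = np.zeros(len(cohort))
    for term, coef in spec.frax_coefficients.items():
        if ":" in term:
            a, b = term.split(":")
            signal += coef * z[a] * z[b]
        else:
            signal += coef * z[term]
    base = cohort["group"].map(
        {g: demo["frax"][g]["mean"] for g in tables.GROUPS}).to_numpy(float)
    frax = base + signal + rng.normal(0, spec.frax_noise_sd, len(cohort))
    lo = cohort["group"].map({g: FRAX_STRATA[g][0] for g in tables.GROUPS})
    hi = cohort["group"].map({g: FRAX_STRATA[g][1] for g in tables.GROUPS})
    cohort["frax"] = np.clip(frax, lo.to_numpy(float), hi.to_numpy(float))
    return cohort
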