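"""Multi-peak fat spectrum and the multi-echo chemical-shift signal model.

The complex gradient-echo signal of a voxel containing water (amplitude W)
and fat (amplitude F) observed at echo time t is modelled as

    s(t) = (W + F * c(t)) * exp(i 2 pi psi t) * exp(-R2* t)
    c(t) = sum_p a_p * exp(i 2 pi f_p t)

where the fat modulation c(t) sums over the peaks of a multi-peak triglyceride
spectrum (relative amplitudes a_p, sum 1; chemical-shift offsets f_p in Hz
relative to water), psi is the B0 field-map off-resonance in Hz and R2* the
shared effective transverse decay rate in 1/s.  This forward model is both
what the phantom simulator evaluates and what the IDEAL reconstruction
inverts.

Echo times are carried in milliseconds (as printed on scanners) and converted
to seconds at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: reduced gyromagnetic ratio of 1H, MHz/T
GAMMA_BAR_MHZ_PER_T = 42.577478518

#: chemical shift of the water resonance, ppm
WATER_PPM = 4.70

#: standard 8-peak triglyceride spectrum: (ppm, relative amplitude).
#: Methyl through olefinic protons; amplitudes normalized to 1.
DEFAULT_PEAKS_PPM = (
    (0.90, 0.088),   # methyl
    (1.30, 0.642),   # bulk methylene
    (1.60, 0.058),   # beta-carboxyl
    (2.02, 0.062),   # allylic
    (2.24, 0.058),   # alpha-carboxyl
    (2.75, 0.006),   # diallylic
    (4.20, 0.039),   # glycerol
    (5.29, 0.047),   # olefinic + glycerol methine
)


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum at a given field strength.

    peaks: sequence of (frequency offset in Hz relative to water,
    relative amplitude); amplitudes are non-negative and sum to 1.
    """

    peaks: tuple[tuple[float, float], ...]
    field_strength: float  # tesla

    def __post_init__(self) -> None:
        amps = np.array([a for _, a in self.peaks], dtype=float)
        if np.any(amps < 0):
            raise ValueError("peak amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > 1e-12:
            raise ValueError("peak amplitudes must sum to 1")

    @property
    def offsets_hz(self) -> np.ndarray:
        return np.array([f for f, _ in self.peaks], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks], dtype=float)

    def modulation(self, tes_s: np.ndarray) -> np.ndarray:
        """Fat modulation c(t) = sum_p a_p exp(i 2 pi f_p t), per echo."""
        t = np.asarray(tes_s, dtype=float)
        return np.exp(2j * np.pi * np.outer(t, self.offsets_hz)) @ self.amplitudes

    def to_yaml(self, path) -> None:
        """Serialize as ppm-offset + amplitude pairs with field strength."""
        hz_per_ppm = GAMMA_BAR_MHZ_PER_T * self.field_strength
        data = {
            "field_strength_T": float(self.field_strength),
            "peaks_ppm_offset_amplitude": [
                [float(f / hz_per_ppm), float(a)] for f, a in self.peaks
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "FatSpectrum":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        b0 = float(data["field_strength_T"])
        hz_per_ppm = GAMMA_BAR_MHZ_PER_T * b0
        peaks = tuple(
            (float(ppm) * hz_per_ppm, float(a))
            for ppm, a in data["peaks_ppm_offset_amplitude"]
        )
        return cls(peaks=peaks, field_strength=b0)


def default_fat_spectrum(field_strength: float = 3.0) -> FatSpectrum:
    """The 8-peak triglyceride spectrum at the given field strength.

    Frequency offsets (Hz, relative to water at 4.70 ppm) scale linearly
    with field strength; most fat peaks lie upfield of water so their
    offsets are negative.
    """
    if field_strength <= 0:
        raise ValueError("field strength must be positive")
    hz_per_ppm = GAMMA_BAR_MHZ_PER_T * field_strength
    peaks = tuple(
        ((ppm - WATER_PPM) * hz_per_ppm, amp) for ppm, amp in DEFAULT_PEAKS_PPM
    )
    return FatSpectrum(peaks=peaks, field_strength=field_strength)


@dataclass(frozen=True)
class EchoTimes:
    """Ordered echo times in milliseconds, strictly increasing and positive."""

    values_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values_ms, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("echo times must be a non-empty 1-D sequence")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")

    @property
    def seconds(self) -> np.ndarray:
        return np.asarray(self.values_ms, dtype=float) * 1e-3

    def __len__(self) -> int:
        return len(self.values_ms)


#: the six-echo scheme of the reference acquisition protocol (ms)
DEFAULT_ECHO_TIMES_MS = (2.1, 2.8, 3.5, 4.5, 5.2, 5.9)
#: the three-echo scheme used during the first year of that protocol
SHORT_ECHO_TIMES_MS = (2.1, 2.8, 3.5)


def default_echo_times(n_echoes: int = 6) -> EchoTimes:
    if n_echoes == 6:
        return EchoTimes(DEFAULT_ECHO_TIMES_MS)
    if n_echoes == 3:
        return EchoTimes(SHORT_ECHO_TIMES_MS)
    raise ValueError("the reference protocol acquired 3 or 6 echoes")


@dataclass(frozen=True)
class VoxelSignalParams:
    """Per-voxel parameters of the chemical-shift signal model."""

    W: float          # water amplitude, arbitrary units, >= 0
    F: float          # fat amplitude, arbitrary units, >= 0
    psi: float = 0.0  # field-map off-resonance, Hz
    r2star: float = 0.0  # decay rate, 1/s, >= 0

    def __post_init__(self) -> None:
        if self.W < 0 or self.F < 0:
            raise ValueError("W and F must be non-negative")
        if self.r2star < 0:
            raise ValueError("r2star must be non-negative")


def simulate_voxel_signal(
    params: VoxelSignalParams, tes: EchoTimes, spectrum: FatSpectrum
) -> np.ndarray:
    """Complex signal of one voxel at each echo time."""
    t = tes.seconds
    c = spectrum.modulation(t)
    return (params.W + params.F * c) * np.exp(
        (2j * np.pi * params.psi - params.r2star) * t
    )


def simulate_signal_maps(
    W: np.ndarray,
    F: np.ndarray,
    psi: np.ndarray,
    r2star: np.ndarray,
    tes: EchoTimes,
    spectrum: FatSpectrum,
) -> np.ndarray:
    """Vectorized forward model: maps of shape S -> signal of shape S + (n_echo,)."""
    t = tes.seconds
    c = spectrum.modulation(t)
    W = np.asarray(W, float)[..., None]
    F = np.asarray(F, float)[..., None]
    psi = np.asarray(psi, float)[..., None]
    r2 = np.asarray(r2star, float)[..., None]
    return (W + F * c) * np.exp((2j * np.pi * psi - r2) * t)


def compute_pdff(
    F: np.ndarray, W: np.ndarray, floor_rel: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Proton density fat fraction PDFF = F / (F + W), with a validity mask.

    Voxels whose total signal F+W falls below ``floor_rel`` times the maximum
    total signal are background-like: their fraction is undefined, so they are
    flagged invalid (and set to 0) rather than allowed to produce NaN.

    Returns (pdff in [0, 1], valid boolean map).
    """
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    if F.shape != W.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs W {W.shape}")
    if np.any(F < 0) or np.any(W < 0):
        raise ValueError("F and W must be non-negative")
    total = F + W
    floor = floor_rel * total.max() if total.size else 0.0
    valid = total > floor
    pdff = np.zeros_like(total)
    np.divide(F, total, out=pdff, where=valid)
    return np.clip(pdff, 0.0, 1.0), valid
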