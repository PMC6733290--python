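"""Terahertz time-domain spectroscopy optical-constant extraction.

Implements the transmission-geometry inversion used to follow molecular
mobility in amorphous solids: a reference pulse (empty cell) and a sample
pulse (slab of thickness ``d``) are Fourier transformed, their complex ratio
``H(omega)`` forms the transfer function, and the thick-slab closed-form
inversion yields the refractive index ``n(omega)`` and absorption
coefficient ``alpha(omega)``::

    n(omega)     = 1 + c |phi(omega)| / (omega d)
    alpha(omega) = -(2/d) ln[ |H(omega)| (n+1)^2 / (4n) ]

with ``phi`` the unwrapped, DC-anchored phase of ``H`` and ``4n/(n+1)^2``
the two-interface Fresnel amplitude transmission.  Fabry-Perot etalon
reflections are neglected, consistent with the forward model in
:mod:`lyoglass.synthetic` (pellets of a few hundred micrometres make the
echoes separable in time, and the mobility analysis uses only the relative
temperature dependence of ``alpha``).

The temperature analysis probes ``alpha`` at 1 THz, where amorphous solids
show high signal-to-noise and no discrete spectral features.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .config import C_CM_PER_PS, ThzSettings
from . import io as lio

__all__ = [
    "THzWaveform",
    "ComplexSpectrum",
    "OpticalConstants",
    "to_spectrum",
    "transfer_function",
    "extract_constants",
    "absorption_at",
    "read_waveform",
    "write_optical_constants",
]


# ---------------------------------------------------------------- containers

@dataclass
class THzWaveform:
    """A single time-domain pulse.

    time is in picoseconds on a uniform, strictly increasing grid; the field
    amplitude is in arbitrary (linear) units.  Sample waveforms carry the
    pellet thickness in centimetres.
    """

    time_ps: np.ndarray
    amplitude: np.ndarray
    role: Literal["reference", "sample"] = "reference"
    temperature_k: float | None = None
    thickness_cm: float | None = None

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time_ps.ndim != 1 or self.time_ps.size != self.amplitude.size:
            raise ValueError("time and amplitude must be 1-D and equal length")
        dt = np.diff(self.time_ps)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
            raise ValueError("time axis must be uniformly sampled")
        if self.role == "sample" and (
            self.thickness_cm is None or self.thickness_cm <= 0
        ):
            raise ValueError("sample waveforms require thickness_cm > 0")

    @property
    def dt_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])


@dataclass
class ComplexSpectrum:
    """One-sided discrete spectrum of a waveform or a transfer function."""

    frequency_thz: np.ndarray
    amplitude: np.ndarray  # complex
    phase_rad: np.ndarray  # unwrapped (and, for waveforms, DC-anchored)
    mask: np.ndarray = field(default=None)  # bins with usable SNR

    def __post_init__(self) -> None:
        self.frequency_thz = np.asarray(self.frequency_thz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.frequency_thz, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude)


@dataclass
class OpticalConstants:
    """Frequency-resolved refractive index and absorption coefficient."""

    frequency_thz: np.ndarray
    n: np.ndarray
    alpha_cm: np.ndarray
    mask: np.ndarray  # True where the extraction is trusted


# ---------------------------------------------------------------- operations

def to_spectrum(
    w: THzWaveform,
    window: float | None = None,
    settings: ThzSettings | None = None,
) -> ComplexSpectrum:
    """Discrete Fourier transform of a waveform with optional tapering.

    Parameters
    ----------
    window:
        ``None`` for no apodisation, otherwise the fraction (0-1] of the
        record length tapered at each end with a half-cosine (Tukey) ramp.

    The phase is unwrapped and anchored: a line is fitted to the unwrapped
    phase over the mid-band (0.2-0.8 THz by default) and the extrapolated
    zero-frequency intercept is removed in integer multiples of 2*pi, which
    resolves the branch ambiguity of the unwrapping without distorting the
    physical phase slope.
    """
    settings = settings or ThzSettings()
    y = w.amplitude
    if y.size < 64:
        raise ValueError("waveform too short (need >= 64 samples)")
    if window is not None:
        if not 0 < window <= 1:
            raise ValueError("window fraction must be in (0, 1]")
        from scipy.signal.windows import tukey

        y = y * tukey(y.size, alpha=window)
    amp = np.fft.rfft(y)
    freq = np.fft.rfftfreq(y.size, d=w.dt_ps)  # 1/ps == THz
    phase = np.unwrap(np.angle(amp))
    lo, hi = settings.phase_anchor_band_thz
    band = (freq >= lo) & (freq <= hi)
    if band.sum() >= 2:
        slope, intercept = np.polyfit(freq[band], phase[band], 1)
        phase = phase - 2 * np.pi * round(intercept / (2 * np.pi))
    mask = np.abs(amp) > settings.noise_floor_fraction * np.max(np.abs(amp))
    return ComplexSpectrum(freq, amp, phase, mask)


def transfer_function(
    sample: ComplexSpectrum, reference: ComplexSpectrum
) -> ComplexSpectrum:
    """Elementwise complex ratio sample/reference on a common frequency axis.

    Bins where the reference magnitude sits below its noise floor are masked
    rather than dividing into noise.
    """
    if sample.frequency_thz.shape != reference.frequency_thz.shape or not np.allclose(
        sample.frequency_thz, reference.frequency_thz
    ):
        raise ValueError("sample and reference must share a frequency axis")
    mask = reference.mask & sample.mask
    ratio = np.zeros_like(sample.amplitude)
    np.divide(sample.amplitude, reference.amplitude, out=ratio, where=mask)
    phase = np.unwrap(np.angle(np.where(mask, ratio, 1.0)))
    # re-anchor the ratio phase the same way as waveform phases
    settings = ThzSettings()
    lo, hi = settings.phase_anchor_band_thz
    band = mask & (sample.frequency_thz >= lo) & (sample.frequency_thz <= hi)
    if band.sum() >= 2:
        _, intercept = np.polyfit(sample.frequency_thz[band], phase[band], 1)
        phase = phase - 2 * np.pi * round(intercept / (2 * np.pi))
    return ComplexSpectrum(sample.frequency_thz, ratio, phase, mask)


def extract_constants(
    H: ComplexSpectrum,
    d_cm: float,
    settings: ThzSettings | None = None,
) -> OpticalConstants:
    """Invert a transfer function to (n, alpha) for a slab of thickness d.

    Bins where the measured |H| exceeds the Fresnel transmission (which
    would imply negative absorption) are flagged in the mask rather than
    raised: they occur routinely at band edges where SNR collapses.
    """
    settings = settings or ThzSettings()
    if d_cm <= 0:
        raise ValueError("thickness must be positive")
    freq = H.frequency_thz
    omega = 2 * np.pi * freq  # rad/ps
    with np.errstate(divide="ignore", invalid="ignore"):
        n = 1.0 + C_CM_PER_PS * np.abs(H.phase_rad) / (omega * d_cm)
    n[freq == 0] = 1.0
    fresnel = 4 * n / (n + 1) ** 2
    mag = H.magnitude
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = -(2.0 / d_cm) * np.log(mag / fresnel)
    lo, hi = settings.usable_band_thz
    mask = H.mask & (freq >= lo) & (freq <= hi)
    mask &= np.isfinite(alpha) & (mag > 0)
    mask &= alpha >= 0  # flag unphysical bins instead of raising
    return OpticalConstants(freq, n, np.nan_to_num(alpha, nan=0.0), mask)


def absorption_at(
    oc: OpticalConstants,
    f_thz: float = 1.0,
    window_thz: float = 0.05,
) -> float:
    """Absorption coefficient at a probe frequency, in cm^-1.

    Averages alpha over ``f +/- window`` (symmetric, so a locally linear
    alpha(f) evaluates exactly at f); falls back to the nearest usable bin
    when the window covers fewer than 3 bins.
    """
    freq = oc.frequency_thz
    usable = freq[oc.mask]
    if usable.size == 0 or not (usable.min() <= f_thz <= usable.max()):
        raise ValueError(f"probe frequency {f_thz} THz outside usable band")
    sel = oc.mask & (np.abs(freq - f_thz) <= window_thz)
    if sel.sum() < 3:
        idx = np.argmin(np.where(oc.mask, np.abs(freq - f_thz), np.inf))
        return float(oc.alpha_cm[idx])
    return float(np.mean(oc.alpha_cm[sel]))


# ----------------------------------------------------------------------- i/o

def read_waveform(path: str | Path) -> THzWaveform:
    df, meta = lio.read_columns(path)
    return THzWaveform(
        time_ps=df.iloc[:, 0].to_numpy(),
        amplitude=df.iloc[:, 1].to_numpy(),
        role=str(meta.get("role", "reference")),  # type: ignore[arg-type]
        temperature_k=meta.get("temperature_k"),  # type: ignore[arg-type]
        thickness_cm=meta.get("thickness_cm"),  # type: ignore[arg-type]
    )


def write_optical_constants(path: str | Path, oc: OpticalConstants) -> None:
    lio.write_columns(
        path,
        {
            "frequency_thz": oc.frequency_thz,
            "n": oc.n,
            "alpha_cm": oc.alpha_cm,
            "mask": oc.mask.astype(float),
        },
        meta={"modality": "optical_constants", "units": "THz, -, cm^-1, bool"},
    )
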