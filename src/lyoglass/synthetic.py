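"""Synthetic-data generators for every input modality.

All downstream stages are testable without instrument data: each generator
produces data with known ground truth, and the THz slab generator doubles
as the forward-model oracle for the optical-constant inversion (the forward
and inverse models share the same physics — two-interface Fresnel
transmission, Beer-Lambert attenuation, no Fabry-Perot echoes).

Conventions:

* every stochastic generator takes an explicit ``seed``; there is no global
  random state, and equal seeds give bit-identical output;
* noise is additive white Gaussian everywhere;
* temperature series default to ~10 K increments over 100-380 K, matching
  typical cryostat heating protocols for lyophilised pellets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np

from .cd import CDSpectrum
from .config import C_CM_PER_PS
from .ftir import Band, FTIRSpectrum
from .nmr import (
    RelaxationSeries,
    T1_DELAY_GRID_S,
    T1RHO_DELAY_GRID_S,
)
from .reference import ReferenceFit
from .thz import THzWaveform
from .transitions import TemperatureSeries
from . import io as lio

__all__ = [
    "PiecewiseModelSpec",
    "SlabSpec",
    "simulate_temperature_series",
    "simulate_thz_pair",
    "simulate_ftir",
    "simulate_relaxation",
    "simulate_cd",
    "amide_band_table",
    "default_excipient_bands",
    "CD_BASIS_SHAPES",
    "cd_basis_curve",
    "piecewise_absorption",
    "write_temperature_series",
    "write_waveform",
    "write_spectrum_table",
]


# ------------------------------------------------- piecewise (transitions)

@dataclass
class PiecewiseModelSpec:
    """Continuous three-segment linear absorption-temperature model.

    The generated curve is continuous at both breakpoints, which makes the
    line intersections recovered by the segmentation coincide exactly with
    the generating breakpoints.
    """

    slopes: tuple[float, float, float]  # cm^-1 K^-1
    tb_low_k: float
    tb_high_k: float
    anchor_cm: float = 5.0  # absorption at the lowest grid temperature
    temperature_k: np.ndarray = field(
        default_factory=lambda: np.arange(100.0, 381.0, 10.0)
    )
    noise_sd_cm: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.temperature_k = np.asarray(self.temperature_k, dtype=float)
        if np.any(np.diff(self.temperature_k) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not self.tb_low_k < self.tb_high_k:
            raise ValueError("breakpoints must satisfy tb_low < tb_high")
        t0, t1 = self.temperature_k[0], self.temperature_k[-1]
        if not (t0 < self.tb_low_k < t1 and t0 < self.tb_high_k < t1):
            raise ValueError("breakpoints must lie strictly inside the grid")

    @classmethod
    def from_reference(
        cls, ref: ReferenceFit, **overrides: object
    ) -> "PiecewiseModelSpec":
        """Spec whose ground truth is a published fit-parameter row."""
        kwargs: dict = dict(
            slopes=ref.slopes, tb_low_k=ref.tg_beta_k, tb_high_k=ref.tg_alpha_k
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def piecewise_absorption(spec: PiecewiseModelSpec, t: np.ndarray) -> np.ndarray:
    """Exact continuous piecewise-linear absorption at temperatures ``t``."""
    t = np.asarray(t, dtype=float)
    m1, m2, m3 = spec.slopes
    t0 = spec.temperature_k[0]
    y_b1 = spec.anchor_cm + m1 * (spec.tb_low_k - t0)
    y_b2 = y_b1 + m2 * (spec.tb_high_k - spec.tb_low_k)
    y = np.where(
        t <= spec.tb_low_k,
        spec.anchor_cm + m1 * (t - t0),
        np.where(
            t <= spec.tb_high_k,
            y_b1 + m2 * (t - spec.tb_low_k),
            y_b2 + m3 * (t - spec.tb_high_k),
        ),
    )
    return y


def simulate_temperature_series(
    spec: PiecewiseModelSpec, min_pts_per_segment: int = 3, label: str = ""
) -> TemperatureSeries:
    """Replicate-averaged absorption-vs-temperature series.

    Returns the mean over ``replicates`` noisy sweeps and the per-point
    standard error of the mean; with ``noise_sd_cm = 0`` the series is the
    exact continuous piecewise line and the SD column is zero.
    """
    t = spec.temperature_k
    if t.size < 3 * min_pts_per_segment:
        raise ValueError("temperature grid too short for three segments")
    truth = piecewise_absorption(spec, t)
    if spec.noise_sd_cm == 0:
        return TemperatureSeries(
            t, truth, np.zeros_like(t), n_replicates=spec.replicates, label=label
        )
    rng = np.random.default_rng(spec.seed)
    draws = truth + rng.normal(0.0, spec.noise_sd_cm, size=(spec.replicates, t.size))
    mean = draws.mean(axis=0)
    sem = (
        draws.std(axis=0, ddof=1) / np.sqrt(spec.replicates)
        if spec.replicates > 1
        else np.full_like(t, spec.noise_sd_cm)
    )
    return TemperatureSeries(t, mean, sem, n_replicates=spec.replicates, label=label)


# ----------------------------------------------------- THz slab (thz_optics)

@dataclass
class SlabSpec:
    """Transmission through a homogeneous slab between empty-cell references.

    ``n`` and ``alpha_cm`` may be constants or callables of frequency (THz).
    The reference pulse is a Gaussian-modulated single-cycle pulse whose
    bandwidth covers ~0.2-2.5 THz.
    """

    thickness_cm: float
    n: float | Callable[[np.ndarray], np.ndarray] = 1.5
    alpha_cm: float | Callable[[np.ndarray], np.ndarray] = 0.0
    pulse_centre_ps: float = 10.0
    pulse_width_ps: float = 0.3  # Gaussian envelope sigma
    carrier_thz: float = 1.0
    n_samples: int = 2048
    dt_ps: float = 0.05
    noise_sd_frac: float = 0.0  # fraction of the reference peak amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("thickness must be positive")

    def n_at(self, f_thz: np.ndarray) -> np.ndarray:
        v = self.n(f_thz) if callable(self.n) else np.full_like(f_thz, float(self.n))
        if np.any(v < 1):
            raise ValueError("refractive index must be >= 1")
        return v

    def alpha_at(self, f_thz: np.ndarray) -> np.ndarray:
        v = (
            self.alpha_cm(f_thz)
            if callable(self.alpha_cm)
            else np.full_like(f_thz, float(self.alpha_cm))
        )
        if np.any(v < 0):
            raise ValueError("absorption coefficient must be >= 0")
        return v


def simulate_thz_pair(
    spec: SlabSpec, temperature_k: float | None = None
) -> tuple[THzWaveform, THzWaveform]:
    """Reference and sample waveforms for a slab measurement.

    The sample pulse is the reference delayed by ``(n-1) d / c`` and scaled
    by the slab amplitude transmission ``4n/(n+1)^2 * exp(-alpha d / 2)``;
    Fabry-Perot echoes are not generated, matching the inversion's neglect
    of them.
    """
    time = spec.dt_ps * np.arange(spec.n_samples)
    envelope = np.exp(-((time - spec.pulse_centre_ps) ** 2) / (2 * spec.pulse_width_ps**2))
    ref = envelope * np.sin(2 * np.pi * spec.carrier_thz * (time - spec.pulse_centre_ps))

    freq = np.fft.rfftfreq(spec.n_samples, d=spec.dt_ps)
    n_f = spec.n_at(freq)
    alpha_f = spec.alpha_at(freq)
    delay = (n_f - 1.0) * spec.thickness_cm / C_CM_PER_PS  # ps, per frequency
    max_delay = float(np.max(delay))
    if spec.pulse_centre_ps + max_delay + 4 * spec.pulse_width_ps > time[-1]:
        raise ValueError("slab delay pushes the pulse outside the time window")
    fresnel = 4 * n_f / (n_f + 1) ** 2
    H = fresnel * np.exp(-alpha_f * spec.thickness_cm / 2.0) * np.exp(
        -1j * 2 * np.pi * freq * delay
    )
    sample = np.fft.irfft(np.fft.rfft(ref) * H, n=spec.n_samples)

    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd_frac * float(np.max(np.abs(ref)))
        ref = ref + rng.normal(0.0, sd, ref.size)
        sample = sample + rng.normal(0.0, sd, sample.size)

    ref_w = THzWaveform(time, ref, role="reference", temperature_k=temperature_k)
    sam_w = THzWaveform(
        time,
        sample,
        role="sample",
        temperature_k=temperature_k,
        thickness_cm=spec.thickness_cm,
    )
    return ref_w, sam_w


# -------------------------------------------------------- FTIR (Gaussians)

#: a ten-component amide-I band layout (centre, sigma, class, in-class
#: weight): low-frequency beta-sheet components, a random-coil component,
#: the helix doublet around the canonical ~1658 position, turns, and the
#: high-frequency beta-sheet shoulders near 1686/1693.  Components of the
#: same class sit close together (smoothing may merge them — harmless for
#: class totals) while adjacent classes are separated by >= 8 cm^-1 so the
#: decomposition's class fractions stay identifiable.
AMIDE_BAND_LAYOUT: tuple[tuple[float, float, str, float], ...] = (
    (1613.0, 3.2, "beta-sheet", 0.20),
    (1622.0, 3.2, "beta-sheet", 0.40),
    (1631.0, 3.2, "beta-sheet", 0.25),
    (1643.0, 3.2, "random", 1.00),
    (1652.0, 3.2, "alpha-helix", 0.50),
    (1660.0, 3.2, "alpha-helix", 0.50),
    (1669.0, 3.2, "turn", 0.55),
    (1676.0, 3.2, "turn", 0.45),
    (1686.0, 3.2, "beta-sheet", 0.08),
    (1693.0, 3.2, "beta-sheet", 0.07),
)


def amide_band_table(fractions: Mapping[str, float]) -> list[Band]:
    """Ten-band amide-I table whose class area fractions are prescribed.

    ``fractions`` maps structure classes to target area fractions (summing
    to 1); within a class the area is split across the layout's components
    by their in-class weights.
    """
    total = sum(fractions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"fractions must sum to 1, got {total}")
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be non-negative")
    bands = []
    for centre, sigma, cls, weight in AMIDE_BAND_LAYOUT:
        class_weight = sum(
            w for _, _, c, w in AMIDE_BAND_LAYOUT if c == cls
        )
        area = fractions.get(cls, 0.0) * weight / class_weight
        bands.append(Band(centre, sigma, area, cls))
    return bands


def default_excipient_bands(scale: float = 1.0) -> list[Band]:
    """Sucrose-like excipient bands, anchored at the isolated 851 cm^-1 band."""
    return [
        Band(851.0, 4.0, 0.30 * scale, "side-chain"),
        Band(995.0, 8.0, 0.50 * scale, "side-chain"),
        Band(1055.0, 10.0, 0.70 * scale, "side-chain"),
        Band(1110.0, 9.0, 0.45 * scale, "side-chain"),
    ]


def _gaussian_sum(x: np.ndarray, bands: list[Band]) -> np.ndarray:
    y = np.zeros_like(x)
    for b in bands:
        amp = b.area / (b.width_cm * np.sqrt(2 * np.pi))
        y += amp * np.exp(-((x - b.centre_cm) ** 2) / (2 * b.width_cm**2))
    return y


def simulate_ftir(
    bands: list[Band],
    excipient_bands: list[Band] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_cm: np.ndarray | None = None,
    label: str = "",
) -> FTIRSpectrum:
    """Gaussian-mixture spectrum plus optional excipient bands and noise."""
    if not bands:
        raise ValueError("band table must be non-empty")
    x = grid_cm if grid_cm is not None else np.arange(800.0, 1801.0, 1.0)
    x = np.asarray(x, dtype=float)
    y = _gaussian_sum(x, bands)
    if excipient_bands:
        y = y + _gaussian_sum(x, excipient_bands)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, x.size)
    return FTIRSpectrum(x, y, label=label)


# ------------------------------------------------------------- NMR (decays)

def simulate_relaxation(
    kind: Literal["T1", "T1rho"],
    m0: float = 1.0,
    a: float = 1.0,
    t_s: float = 1.0,
    delays_s: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    component: str = "protein",
    label: str = "",
) -> RelaxationSeries:
    """Noisy magnetisation series following the relaxation model exactly.

    Default delay grids are the standard 8-point grids (0.01-5 s for
    inversion recovery, 0.1-50 ms for the spin lock).
    """
    if t_s <= 0:
        raise ValueError("relaxation time must be positive")
    if delays_s is None:
        delays_s = T1_DELAY_GRID_S if kind == "T1" else T1RHO_DELAY_GRID_S
    delays_s = np.asarray(delays_s, dtype=float)
    if delays_s.size == 0:
        raise ValueError("delay grid must be non-empty")
    if kind == "T1":
        m = m0 * (1.0 - 2.0 * a * np.exp(-delays_s / t_s))
    else:
        m = m0 * np.exp(-delays_s / t_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m + rng.normal(0.0, noise_sd, m.size)
    return RelaxationSeries(delays_s, m, kind=kind, component=component, label=label)


# --------------------------------------------------------------- CD (bases)

#: parameterised basis-band shapes per structure class:
#: (centre nm, sigma nm, signed amplitude), on a mean-residue-ellipticity-like
#: scale.  Helix: double minima 208/222 and a strong positive 193 band; sheet:
#: single broad 218 minimum with a weaker positive band near 196; random coil:
#: deep minimum near 198.
CD_BASIS_SHAPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "helix": ((193.0, 4.0, 24.0), (208.0, 5.5, -20.0), (222.0, 6.0, -20.0)),
    "sheet": ((196.0, 5.0, 16.0), (218.0, 7.0, -26.0)),
    "random": ((198.0, 7.0, -30.0), (220.0, 10.0, 2.0)),
}


def cd_basis_curve(cls: str, wavelength_nm: np.ndarray) -> np.ndarray:
    """Evaluate one class's basis spectrum on a wavelength grid."""
    y = np.zeros_like(wavelength_nm)
    for centre, sigma, amp in CD_BASIS_SHAPES[cls]:
        y += amp * np.exp(-((wavelength_nm - centre) ** 2) / (2 * sigma**2))
    return y


def simulate_cd(
    fractions: Mapping[str, float],
    basis: Mapping[str, tuple[tuple[float, float, float], ...]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> CDSpectrum:
    """Mixture of class basis spectra over 190-250 nm at 0.5 nm steps."""
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be non-negative")
    if not np.isclose(sum(fractions.values()), 1.0, atol=1e-6):
        raise ValueError("fractions must sum to 1")
    shapes = dict(CD_BASIS_SHAPES)
    if basis:
        shapes.update(basis)
    wl = np.arange(190.0, 250.5, 0.5)
    y = np.zeros_like(wl)
    for cls, frac in fractions.items():
        if cls not in shapes:
            raise KeyError(f"no basis shape for class {cls!r}")
        curve = np.zeros_like(wl)
        for centre, sigma, amp in shapes[cls]:
            curve += amp * np.exp(-((wl - centre) ** 2) / (2 * sigma**2))
        y += frac * curve
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, wl.size)
    return CDSpectrum(wl, y, label=label)


# --------------------------------------------------------------- writers

def write_temperature_series(
    path, series: TemperatureSeries, meta: Mapping[str, object] | None = None
) -> None:
    base = {"modality": "temperature_series", "units": "K, cm^-1, cm^-1"}
    base.update(meta or {})
    lio.write_columns(
        path,
        {
            "temperature_k": series.temperature_k,
            "absorption_cm": series.absorption_cm,
            "sd_cm": series.sd_cm
            if series.sd_cm is not None
            else np.zeros_like(series.temperature_k),
        },
        base,
    )


def write_waveform(path, w: THzWaveform, meta: Mapping[str, object] | None = None) -> None:
    base: dict[str, object] = {"modality": "thz_waveform", "units": "ps, a.u.", "role": w.role}
    if w.temperature_k is not None:
        base["temperature_k"] = w.temperature_k
    if w.thickness_cm is not None:
        base["thickness_cm"] = w.thickness_cm
    base.update(meta or {})
    lio.write_columns(path, {"time_ps": w.time_ps, "amplitude": w.amplitude}, base)


def write_spectrum_table(
    path, x: np.ndarray, y: np.ndarray, modality: str, units: str,
    meta: Mapping[str, object] | None = None,
) -> None:
    base = {"modality": modality, "units": units}
    base.update(meta or {})
    lio.write_columns(path, {"x": x, "y": y}, base)
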