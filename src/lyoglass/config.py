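"""Run-time configuration for all analysis stages.

Every disclosed analysis constant (probe frequency, spectral windows,
band-class boundaries, statistical thresholds, the moisture QC gate) lives
here as a validated, overridable setting with its default taken from the
published analysis conventions this package implements.  Configuration can
be loaded from a YAML file; unknown keys are rejected so typos fail loudly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

logger = logging.getLogger("lyoglass")

#: speed of light in cm/ps — the natural unit system for THz-TDS, where time
#: is measured in picoseconds, frequency in THz and lengths in centimetres.
C_CM_PER_PS = 0.0299792458


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThzSettings(_Section):
    """Terahertz optical-constant extraction settings."""

    probe_frequency_thz: float = 1.0
    #: half-width of the averaging window around the probe frequency (THz)
    probe_window_thz: float = 0.05
    #: band used to anchor the unwrapped phase by linear extrapolation to DC
    phase_anchor_band_thz: Tuple[float, float] = (0.2, 0.8)
    #: usable band for optical constants; outside it values are masked
    usable_band_thz: Tuple[float, float] = (0.3, 2.0)
    #: reference bins with magnitude below this fraction of the peak are masked
    noise_floor_fraction: float = 1e-3


class TransitionSettings(_Section):
    """Three-region glass-transition segmentation settings."""

    min_points_per_region: int = 3
    #: confined requires m3 < confinement_ratio * m2 ...
    confinement_ratio: float = 1.0
    #: ... and (m2 - m3) > confinement_z * sqrt(SE2^2 + SE3^2).  A deliberately
    #: conservative default: region-3 slopes are often poorly determined and a
    #: lower threshold overcalls confinement on noise.
    confinement_z: float = 5.0
    #: relative slope-difference tolerance below which lines are parallel
    parallel_rtol: float = 1e-6
    #: hysteresis flag threshold on |delta m3| in combined-SE units
    hysteresis_z: float = 2.0


class FtirSettings(_Section):
    """Amide-I secondary-structure deconvolution settings."""

    #: amide I region; the conventional 1600-1700 cm^-1 window
    amide_window_cm: Tuple[float, float] = (1600.0, 1700.0)
    #: Savitzky-Golay window expressed in wavenumber units
    sg_width_cm: float = 14.0
    sg_polyorder: int = 3
    n_bands: int = 10
    #: fallback starting sigma for components not seen as distinct minima
    init_width_cm: float = 3.5
    #: physical sigma range of amide-I components; wide bands straddling
    #: class boundaries would defeat centre-based assignment
    width_bounds_cm: Tuple[float, float] = (2.0, 6.0)
    #: fitted centres may move at most this far from their starting position
    centre_halfwidth_cm: float = 3.0
    excipient_anchor_cm: float = 851.0
    anchor_halfwidth_cm: float = 5.0
    #: band-class boundaries (half-open intervals [lo, hi) on peak centres).
    #: Anchors: helix ~1658, low-frequency sheet ~1640, turn ~1670,
    #: high-frequency sheet ~1690, random coil between sheet and helix.
    class_bounds: dict[str, list[Tuple[float, float]]] = {
        "beta-sheet": [(1600.0, 1640.0), (1680.0, 1695.0)],
        "random": [(1640.0, 1646.0)],
        "alpha-helix": [(1646.0, 1665.0)],
        "turn": [(1665.0, 1680.0)],
    }

    @field_validator("amide_window_cm")
    @classmethod
    def _window_ordered(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        if v[0] >= v[1]:
            raise ValueError("amide window must be (low, high)")
        return v


class CdSettings(_Section):
    """CD signature-classification settings (wavelengths in nm)."""

    helix_minima_nm: Tuple[float, float] = (208.0, 222.0)
    helix_minima_tol_nm: float = 3.0
    helix_positive_nm: float = 193.0
    helix_positive_tol_nm: float = 2.0
    sheet_minimum_nm: float = 218.0
    sheet_minimum_tol_nm: float = 4.0


class NmrSettings(_Section):
    """Relaxation fitting and phase-homogeneity settings."""

    #: upper bound on the inversion-recovery correction factor A
    a_max: float = 1.2
    #: |delta T| <= z * combined SE counts as homogeneous
    homogeneity_z: float = 2.0
    max_restarts: int = 3


class QcSettings(_Section):
    moisture_threshold_pct: float = 2.5


class AnalysisConfig(_Section):
    """Top-level configuration aggregating every stage's settings."""

    thz: ThzSettings = ThzSettings()
    transitions: TransitionSettings = TransitionSettings()
    ftir: FtirSettings = FtirSettings()
    cd: CdSettings = CdSettings()
    nmr: NmrSettings = NmrSettings()
    qc: QcSettings = QcSettings()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for report provenance."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def log_disclosed_assumptions(config: AnalysisConfig) -> None:
    """Emit one WARN per run for every disclosed analysis assumption."""
    logger.warning(
        "amide I window set to %s cm^-1 (conventional window; configurable)",
        config.ftir.amide_window_cm,
    )
    logger.warning(
        "THz phase anchored by linear extrapolation of the %s THz band to DC",
        config.thz.phase_anchor_band_thz,
    )
    logger.warning(
        "confinement call requires slope decrease > %g combined SEs",
        config.transitions.confinement_z,
    )


DEFAULT_CONFIG = AnalysisConfig()
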