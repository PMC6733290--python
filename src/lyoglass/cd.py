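"""Circular dichroism: mean residue ellipticity and signature classification.

For re-dissolved lyophilised protein the CD spectrum is reduced to the mean
residue ellipticity

    [theta](lambda) = theta_obs(lambda) / (l * c * n)

with ``theta_obs`` the observed ellipticity (mdeg), ``l`` the path length in
**millimetres**, ``c`` the molar concentration (M) and ``n`` the number of
residues (583 for BSA, 1330 for the IgG1 antibody studied here).  The
formula is applied literally with ``l`` in mm — this embeds the
conventional factor of ten relative to centimetre-based definitions, so the
unit provenance is recorded on the result to avoid silent misuse.

Classification is qualitative: double minima at 208/222 nm plus a positive
band at 193 nm mark a helix-rich protein; a single broad minimum near
218 nm marks a sheet-rich one; anything else is indeterminate.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .config import CdSettings
from . import io as lio

__all__ = [
    "CDSpectrum",
    "MREResult",
    "subtract_blank",
    "mean_residue_ellipticity",
    "classify_signature",
    "average_accumulations",
    "read_cd",
]

Signature = Literal["helix-rich", "sheet-rich", "indeterminate"]


@dataclass
class CDSpectrum:
    """Observed ellipticity (mdeg) on a uniform wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    theta_obs_mdeg: np.ndarray
    accumulations: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.theta_obs_mdeg = np.asarray(self.theta_obs_mdeg, dtype=float)
        if self.wavelength_nm.size != self.theta_obs_mdeg.size:
            raise ValueError("wavelength and ellipticity must match in length")
        step = np.diff(self.wavelength_nm)
        if step.size and (np.any(step <= 0) or np.ptp(step) > 1e-9 * step[0]):
            raise ValueError("wavelength grid must be uniform and increasing")


@dataclass
class MREResult:
    """Mean residue ellipticity with its normalisation provenance."""

    wavelength_nm: np.ndarray
    mre: np.ndarray  # deg cm^2 dmol^-1 under the mm-path convention
    path_length_mm: float
    concentration_m: float
    n_residues: int
    units_note: str = (
        "[theta] = theta_obs(mdeg) / (l[mm] * c[M] * n); mm-path convention"
    )


def subtract_blank(sample: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    """Pointwise blank (solvent) subtraction on a shared grid."""
    if sample.wavelength_nm.shape != blank.wavelength_nm.shape or not np.allclose(
        sample.wavelength_nm, blank.wavelength_nm
    ):
        raise ValueError("sample and blank grids differ")
    return CDSpectrum(
        sample.wavelength_nm,
        sample.theta_obs_mdeg - blank.theta_obs_mdeg,
        accumulations=sample.accumulations,
        label=sample.label,
    )


def average_accumulations(spectra: list[CDSpectrum]) -> tuple[CDSpectrum, np.ndarray]:
    """Pointwise mean over repeated accumulations, with the per-point SD."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavelength_nm
    stack = np.stack([s.theta_obs_mdeg for s in spectra])
    mean = CDSpectrum(
        grid, stack.mean(axis=0), accumulations=len(spectra), label=spectra[0].label
    )
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(grid)
    return mean, sd


def mean_residue_ellipticity(
    s: CDSpectrum, path_length_mm: float, concentration_m: float, n_residues: int
) -> MREResult:
    """Normalise observed ellipticity to mean residue ellipticity."""
    if path_length_mm <= 0 or concentration_m <= 0 or n_residues <= 0:
        raise ValueError("path length, concentration and residue count must be > 0")
    return MREResult(
        wavelength_nm=s.wavelength_nm,
        mre=s.theta_obs_mdeg / (path_length_mm * concentration_m * n_residues),
        path_length_mm=path_length_mm,
        concentration_m=concentration_m,
        n_residues=n_residues,
    )


def _local_minima(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1
    return x[idx]


def classify_signature(
    m: MREResult, settings: CdSettings | None = None
) -> Signature:
    """Gross secondary-structure signature from band positions.

    helix-rich: local minima near both 208 and 222 nm and a positive value
    at 193 nm.  sheet-rich: a single dominant minimum near 218 nm with
    neither helix condition met.  Otherwise indeterminate (including flat
    spectra and ambiguous mixtures).
    """
    settings = settings or CdSettings()
    wl, y = m.wavelength_nm, m.mre
    if wl.min() > 193.0 - settings.helix_positive_tol_nm or wl.max() < 222.0:
        raise ValueError("spectrum must cover 193-222 nm for classification")
    if np.allclose(y, 0.0):
        return "indeterminate"
    minima = _local_minima(wl, y)
    deep = minima[
        y[np.searchsorted(wl, minima)] < 0
    ]  # only negative-going minima count as CD bands

    def has_min(target: float, tol: float) -> bool:
        return bool(np.any(np.abs(deep - target) <= tol))

    m208, m222 = settings.helix_minima_nm
    helix_min_208 = has_min(m208, settings.helix_minima_tol_nm)
    helix_min_222 = has_min(m222, settings.helix_minima_tol_nm)
    sel = np.abs(wl - settings.helix_positive_nm) <= settings.helix_positive_tol_nm
    helix_positive = bool(np.any(y[sel] > 0))
    if helix_min_208 and helix_min_222 and helix_positive:
        return "helix-rich"
    sheet_min = deep[
        np.abs(deep - settings.sheet_minimum_nm) <= settings.sheet_minimum_tol_nm
    ]
    single_dominant = deep.size >= 1 and sheet_min.size == deep.size
    if single_dominant and not (helix_min_208 or helix_min_222):
        return "sheet-rich"
    return "indeterminate"


def read_cd(path: str | Path) -> CDSpectrum:
    df, meta = lio.read_columns(path)
    return CDSpectrum(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].to_numpy(),
        accumulations=int(meta.get("accumulations", 1)),  # type: ignore[arg-type]
        label=str(meta.get("label", Path(path).stem)),
    )
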