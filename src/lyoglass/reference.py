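"""Published analysis parameters for the lyophilised-formulation study set.

These tabulated three-region fit parameters (slope +/- SE per temperature
region, in cm^-1 K^-1, and the transition temperatures in K) and secondary
structure fractions for the seven BSA/mAb1 formulations, neat BSA and a
sucrose/glycine excipient mixture serve as ground truth for the synthetic
generator and as fixtures for round-trip validation of the analysis chain.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceFit:
    """Three-region fit parameters for one formulation."""

    label: str
    slopes: tuple[float, float, float]  # cm^-1 K^-1
    slope_ses: tuple[float, float, float]
    tg_beta_k: float
    tg_alpha_k: float
    tg_dsc_k: float | None
    confined: bool  # high-temperature absorption plateau observed


REFERENCE_FITS: dict[str, ReferenceFit] = {
    r.label: r
    for r in [
        ReferenceFit("F1", (0.033, 0.062, 0.021), (0.00059, 0.0018, 0.0036), 262, 336, 310, True),
        ReferenceFit("F2", (0.021, 0.054, 0.023), (0.0020, 0.0028, 0.0027), 219, 339, 311, True),
        ReferenceFit("F3", (0.027, 0.074, 0.0051), (0.0091, 0.0016, 0.0028), 217, 318, 302, True),
        ReferenceFit("F4", (0.00014, 0.028, 0.048), (0.0017, 0.0011, 0.0014), 205, 298, 305, False),
        ReferenceFit("neat BSA", (0.034, 0.071, 0.12), (0.0031, 0.0017, 0.0023), 216, 331, None, False),
        ReferenceFit("sucrose and glycine mixture", (0.011, 0.047, 0.070), (0.0014, 0.0021, 0.0018), 220, 303, None, False),
        ReferenceFit("F5", (0.00056, 0.061, 0.020), (0.0050, 0.0020, 0.011), 151, 272, 282, False),
        ReferenceFit("F6", (0.0033, 0.023, 0.053), (0.0034, 0.00087, 0.0021), 135, 262, 297, False),
        ReferenceFit("F7", (0.0038, 0.067, 0.020), (0.0047, 0.0011, 0.0046), 168, 334, 304, True),
    ]
}

#: reported secondary-structure fractions (percent) from amide-I analysis
FTIR_REFERENCE_PCT = {
    ("neat BSA", "alpha-helix"): 15.0,
    ("F2 unheated", "alpha-helix"): 36.0,
    ("F2 heated", "alpha-helix"): 41.0,
    ("F4 unheated", "alpha-helix"): 40.0,
    ("F6 unheated", "beta-sheet"): 56.0,
}

#: residue counts used for mean residue ellipticity
RESIDUE_COUNTS = {"BSA": 583, "mAb1": 1330}
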