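"""Per-formulation orchestration: QC gate, per-modality stages, reporting.

A :class:`FormulationRecord` carries composition metadata (components,
protein, residual moisture); :func:`run_formulation` applies the moisture
QC gate (vials must hold < 2.5 % w/w residual water), runs whichever
modality analyses have inputs, and collects everything into a JSON-safe
:class:`FormulationReport`.  A single failing stage never aborts the run —
its error is recorded and the remaining stages proceed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cd as cd_mod
from . import ftir as ftir_mod
from . import nmr as nmr_mod
from . import thz as thz_mod
from . import transitions as tr_mod
from .config import AnalysisConfig, DEFAULT_CONFIG, log_disclosed_assumptions

__all__ = [
    "Component",
    "FormulationRecord",
    "FormulationInputs",
    "FormulationReport",
    "qc_moisture",
    "run_formulation",
    "summarise",
    "report_to_json",
    "report_from_json",
]

logger = logging.getLogger("lyoglass")

QcStatus = Literal["pass", "fail", "unknown"]


class Component(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    concentration: float = Field(gt=0)
    unit: str = "mM"


class FormulationRecord(BaseModel):
    """Composition metadata for one lyophilised formulation."""

    model_config = ConfigDict(extra="forbid")
    label: str
    components: list[Component] = []
    protein: str = "other"  # BSA | mAb1 | other
    residual_moisture_pct: Optional[float] = Field(default=None, ge=0, le=100)
    tg_dsc_k: Optional[float] = None  # calorimetric reference value, if known


@dataclasses.dataclass
class FormulationInputs:
    """Paths (or in-memory objects) for whichever modalities were measured."""

    thz_series: "str | Path | tr_mod.TemperatureSeries | None" = None
    ftir_sample: "str | Path | ftir_mod.FTIRSpectrum | None" = None
    ftir_excipient: "str | Path | ftir_mod.FTIRSpectrum | None" = None
    cd_sample: "str | Path | cd_mod.CDSpectrum | None" = None
    cd_blank: "str | Path | cd_mod.CDSpectrum | None" = None
    cd_path_mm: float = 1.0
    cd_concentration_m: float = 3e-6
    cd_residues: int = 583
    nmr_series: "list[str | Path | nmr_mod.RelaxationSeries] | None" = None

    def any_present(self) -> bool:
        return any(
            v is not None
            for v in (self.thz_series, self.ftir_sample, self.cd_sample, self.nmr_series)
        )


@dataclasses.dataclass
class FormulationReport:
    """JSON-serialisable result bundle for one formulation."""

    label: str
    qc_status: QcStatus
    transitions: dict[str, Any] | None = None
    secondary_structure: dict[str, Any] | None = None
    cd_classification: str | None = None
    relaxation: dict[str, Any] | None = None
    stage_errors: dict[str, str] = dataclasses.field(default_factory=dict)
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)


def qc_moisture(
    record: FormulationRecord, threshold_pct: float = 2.5
) -> QcStatus:
    """Residual-moisture gate: pass iff moisture is strictly below threshold.

    Missing moisture values warn and pass through with ``unknown`` status
    rather than blocking the analysis.
    """
    if record.residual_moisture_pct is None:
        logger.warning("%s: residual moisture unknown; QC status 'unknown'", record.label)
        return "unknown"
    return "pass" if record.residual_moisture_pct < threshold_pct else "fail"


def _load_series(obj) -> tr_mod.TemperatureSeries:
    if isinstance(obj, tr_mod.TemperatureSeries):
        return obj
    from . import io as lio

    df, meta = lio.read_columns(obj)
    sd = df.iloc[:, 2].to_numpy() if df.shape[1] > 2 else None
    if sd is not None and not np.any(sd > 0):
        sd = None
    return tr_mod.TemperatureSeries(
        df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), sd,
        label=str(meta.get("label", Path(str(obj)).stem)),
    )


def _load_ftir(obj) -> ftir_mod.FTIRSpectrum:
    return obj if isinstance(obj, ftir_mod.FTIRSpectrum) else ftir_mod.read_spectrum(obj)


def _load_cd(obj) -> cd_mod.CDSpectrum:
    return obj if isinstance(obj, cd_mod.CDSpectrum) else cd_mod.read_cd(obj)


def _load_nmr(obj) -> nmr_mod.RelaxationSeries:
    return obj if isinstance(obj, nmr_mod.RelaxationSeries) else nmr_mod.read_relaxation(obj)


def _fit_to_dict(r: tr_mod.PiecewiseFitResult) -> dict[str, Any]:
    return {
        "slopes": list(r.slopes),
        "slope_ses": list(r.slope_ses),
        "intercepts": [reg.intercept for reg in r.regions],
        "break_indices": list(r.break_indices),
        "region_counts": list(r.region_counts),
        "tg_beta_k": r.tg_beta_k,
        "tg_alpha_k": r.tg_alpha_k,
        "sse": r.sse,
        "mobility_class": r.mobility_class,
        "weighted": r.weighted,
    }


def run_formulation(
    record: FormulationRecord,
    inputs: FormulationInputs,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> FormulationReport:
    """Run every stage with available inputs and assemble the report.

    Deterministic for fixed config and seed; stage failures are caught and
    recorded per stage.
    """
    config = config or DEFAULT_CONFIG
    if not inputs.any_present():
        raise ValueError("no modality inputs provided")
    log_disclosed_assumptions(config)
    report = FormulationReport(
        label=record.label,
        qc_status=qc_moisture(record, config.qc.moisture_threshold_pct),
        provenance={
            "config_hash": config.config_hash(),
            "seed": seed,
            "inputs": {
                k: str(v)
                for k, v in dataclasses.asdict(inputs).items()
                if v is not None and not isinstance(v, (int, float))
            },
        },
    )

    if inputs.thz_series is not None:
        try:
            series = _load_series(inputs.thz_series)
            fit = tr_mod.fit_three_regions(
                series, config.transitions.min_points_per_region, config.transitions
            )
            report.transitions = _fit_to_dict(fit)
        except Exception as exc:  # single-stage failure must not abort the run
            report.stage_errors["transitions"] = f"{type(exc).__name__}: {exc}"

    if inputs.ftir_sample is not None:
        try:
            sample = _load_ftir(inputs.ftir_sample)
            excipient = (
                _load_ftir(inputs.ftir_excipient)
                if inputs.ftir_excipient is not None
                else None
            )
            est = ftir_mod.estimate_secondary_structure(
                sample, excipient, config.ftir, seed=seed
            )
            report.secondary_structure = {
                "fractions_pct": est.fractions_pct,
                "bands": [dataclasses.asdict(b) for b in est.bands],
                "amide_window_cm": list(est.amide_window_cm),
            }
        except Exception as exc:
            report.stage_errors["ftir"] = f"{type(exc).__name__}: {exc}"

    if inputs.cd_sample is not None:
        try:
            sample = _load_cd(inputs.cd_sample)
            if inputs.cd_blank is not None:
                sample = cd_mod.subtract_blank(sample, _load_cd(inputs.cd_blank))
            mre = cd_mod.mean_residue_ellipticity(
                sample, inputs.cd_path_mm, inputs.cd_concentration_m, inputs.cd_residues
            )
            report.cd_classification = cd_mod.classify_signature(mre, config.cd)
        except Exception as exc:
            report.stage_errors["cd"] = f"{type(exc).__name__}: {exc}"

    if inputs.nmr_series:
        fits: dict[str, Any] = {}
        calls: dict[str, Any] = {}
        try:
            loaded = [_load_nmr(s) for s in inputs.nmr_series]
            by_key: dict[tuple[str, str], nmr_mod.RelaxationFit] = {}
            for s in loaded:
                fit = nmr_mod.fit_relaxation(s, config.nmr)
                by_key[(s.kind, s.component)] = fit
                fits[f"{s.kind}/{s.component}"] = {
                    "t_s": fit.t_s,
                    "t_se_s": fit.t_se_s,
                    "m0": fit.m0,
                    "a": fit.a,
                    "converged": fit.converged,
                }
            for kind in ("T1", "T1rho"):
                pk, sk = (kind, "protein"), (kind, "sugar")
                if pk in by_key and sk in by_key:
                    call = nmr_mod.phase_homogeneity(by_key[pk], by_key[sk], config.nmr)
                    calls[kind] = {
                        "delta_t_s": call.delta_t_s,
                        "combined_se_s": call.combined_se_s,
                        "homogeneous": call.homogeneous,
                        "length_scale": call.length_scale,
                    }
            report.relaxation = {"fits": fits, "homogeneity": calls}
        except Exception as exc:
            report.stage_errors["nmr"] = f"{type(exc).__name__}: {exc}"

    return report


def report_to_json(report: FormulationReport) -> str:
    return json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True)


def report_from_json(text: str) -> FormulationReport:
    data = json.loads(text)
    return FormulationReport(**data)


def summarise(reports: list[FormulationReport]) -> pd.DataFrame:
    """Cross-formulation study table: fit parameters, class, QC status.

    Repeated labels are suffixed deterministically; missing sections yield
    NA columns.
    """
    if not reports:
        raise ValueError("need at least one report")
    seen: dict[str, int] = {}
    rows = []
    for rep in reports:
        label = rep.label
        if label in seen:
            seen[label] += 1
            label = f"{label}_{seen[rep.label]}"
        else:
            seen[label] = 0
        row: dict[str, Any] = {"label": label, "qc_status": rep.qc_status}
        tr = rep.transitions or {}
        slopes = tr.get("slopes", [np.nan] * 3)
        ses = tr.get("slope_ses", [np.nan] * 3)
        for k in range(3):
            row[f"m{k + 1}"] = slopes[k]
            row[f"m{k + 1}_se"] = ses[k]
        row["tg_beta_k"] = tr.get("tg_beta_k", np.nan)
        row["tg_alpha_k"] = tr.get("tg_alpha_k", np.nan)
        row["mobility_class"] = tr.get("mobility_class", pd.NA)
        ss = (rep.secondary_structure or {}).get("fractions_pct", {})
        row["helix_pct"] = ss.get("alpha-helix", np.nan)
        row["sheet_pct"] = ss.get("beta-sheet", np.nan)
        row["cd_class"] = rep.cd_classification or pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
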