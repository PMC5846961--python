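"""Configuration handling and the full-report entry point.

All tunable quantities — the health-state utilities, the logistic-model
coefficients (or the printed constraints to re-derive them from), the
instrument-to-utility maps, PSA standard errors and tolerances — live in a
single YAML file with a versioned schema.  The shipped defaults reproduce
the original study's published values and are study-, surgeon- and
panel-specific: validate them before any clinical use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import pandas as pd
import yaml

from .cosmesis import PatientPresentation, TumorLocation
from .prediction import (
    CosmesisLogisticModel,
    auc,
    calibrate_from_printed_values,
    confusion_at_threshold,
)
from .decision import decision_graph, benefit, harm, ratio_cutoff, treatment_threshold
from .uncertainty import run_psa
from .utilities import HealthStateUtilities, LinearUtilityMap

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "default_model",
    "default_utilities",
    "run_full_report",
    "render_report_text",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """The configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    utilities: HealthStateUtilities
    model: CosmesisLogisticModel
    calibration: Optional[dict]
    maps: tuple[LinearUtilityMap, ...]
    psa_n: int
    psa_seed: int
    psa_standard_errors: Mapping[str, float]
    indifference_tolerance: float
    reference_patient: PatientPresentation
    schema_version: int = SCHEMA_VERSION


def _require_keys(section: Mapping, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = required - set(section)
    if missing:
        raise ConfigError(f"missing keys in {where}: {sorted(missing)}")


def _parse(raw: Mapping) -> RunConfig:
    _require_keys(
        raw,
        allowed={
            "schema_version", "utilities", "model", "calibration", "maps",
            "psa", "tolerances", "reference_patient",
        },
        required={"schema_version", "utilities", "model"},
        where="config root",
    )
    if int(raw["schema_version"]) != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {raw['schema_version']} (expected {SCHEMA_VERSION})"
        )

    usec = raw["utilities"]
    _require_keys(
        usec,
        allowed={"u_bcs_good", "u_bcs_poor", "u_mst_only", "u_mst_recon", "p_recon"},
        required={"u_bcs_good", "u_bcs_poor", "u_mst_only", "u_mst_recon", "p_recon"},
        where="utilities",
    )
    utilities = HealthStateUtilities(**{k: float(v) for k, v in usec.items()}).validate()

    calibration = raw.get("calibration")
    if raw["model"] == "derive-from-printed":
        if calibration is None:
            raise ConfigError("model 'derive-from-printed' requires a calibration section")
        _require_keys(
            calibration,
            allowed={"threshold_prob", "cutoffs", "anchor"},
            required={"threshold_prob", "cutoffs", "anchor"},
            where="calibration",
        )
        model = calibrate_from_printed_values(
            cutoffs={TumorLocation(k): float(v) for k, v in calibration["cutoffs"].items()},
            threshold_prob=float(calibration["threshold_prob"]),
            anchor=(
                TumorLocation(calibration["anchor"]["location"]),
                float(calibration["anchor"]["ratio"]),
                float(calibration["anchor"]["probability"]),
            ),
        )
    elif isinstance(raw["model"], Mapping):
        model = CosmesisLogisticModel.from_dict(raw["model"])
    else:
        raise ConfigError(
            "model must be 'derive-from-printed' or a mapping of coefficients, "
            f"got {raw['model']!r}"
        )

    maps = []
    for i, m in enumerate(raw.get("maps") or []):
        _require_keys(
            m,
            allowed={"instrument", "intercept", "coefficients", "clamp"},
            required={"intercept", "coefficients"},
            where=f"maps[{i}]",
        )
        maps.append(
            LinearUtilityMap(
                intercept=float(m["intercept"]),
                coefficients={str(k): float(v) for k, v in m["coefficients"].items()},
                clamp=bool(m.get("clamp", True)),
                instrument=str(m.get("instrument", "")),
            )
        )

    psa = raw.get("psa") or {}
    _require_keys(psa, allowed={"n", "seed", "standard_errors"}, required=set(), where="psa")
    tol = raw.get("tolerances") or {}
    _require_keys(tol, allowed={"indifference"}, required=set(), where="tolerances")

    ref = raw.get("reference_patient") or {
        "tumor_volume_cm3": 3.8,
        "breast_volume_cm3": 675.0,
        "location": "upper_medial",
    }
    _require_keys(
        ref,
        allowed={"tumor_volume_cm3", "breast_volume_cm3", "location"},
        required={"tumor_volume_cm3", "breast_volume_cm3", "location"},
        where="reference_patient",
    )

    return RunConfig(
        utilities=utilities,
        model=model,
        calibration=dict(calibration) if calibration else None,
        maps=tuple(maps),
        psa_n=int(psa.get("n", 10_000)),
        psa_seed=int(psa.get("seed", 0)),
        psa_standard_errors={str(k): float(v) for k, v in (psa.get("standard_errors") or {}).items()},
        indifference_tolerance=float(tol.get("indifference", 1e-12)),
        reference_patient=PatientPresentation(
            tumor_volume=float(ref["tumor_volume_cm3"]),
            breast_volume=float(ref["breast_volume_cm3"]),
            location=TumorLocation(ref["location"]),
        ),
    )


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return _parse(raw)


def default_config() -> RunConfig:
    """The shipped study-default configuration."""
    text = resources.files("bcsdecision.data").joinpath("default_config.yaml").read_text()
    return _parse(yaml.safe_load(text))


def default_model() -> CosmesisLogisticModel:
    """The versioned derived-default coefficients shipped with the package."""
    text = resources.files("bcsdecision.data").joinpath("derived_model.yaml").read_text()
    return CosmesisLogisticModel.from_dict(yaml.safe_load(text)["coefficients"])


def default_utilities() -> HealthStateUtilities:
    return default_config().utilities


def run_full_report(config: RunConfig, cohort: Optional[pd.DataFrame] = None) -> dict:
    """Run the whole pipeline under one configuration and collect a report.

    Sections: derived model coefficients with their provenance, benefit /
    harm / threshold, the per-location ratio cut-off table, a decision-graph
    grid, cohort diagnostics (AUC, confusion counts, predictive values) when
    a cohort is supplied, and a PSA summary.  JSON-serialisable throughout.
    """
    utils = config.utilities
    thr = treatment_threshold(utils)
    cutoff_threshold = (
        float(config.calibration["threshold_prob"]) if config.calibration else thr
    )
    cutoffs = {
        loc.value: ratio_cutoff(config.model, cutoff_threshold, loc) for loc in TumorLocation
    }
    grid = decision_graph(
        config.model, utils, [r / 2 for r in range(1, 61)]
    )
    report = {
        "schema_version": config.schema_version,
        "model": {
            "coefficients": config.model.to_dict(),
            "provenance": (
                "derived from printed per-location cut-offs and the worked-example anchor"
                if config.calibration
                else "supplied directly in configuration"
            ),
            "calibration_inputs": config.calibration,
        },
        "utilities": {
            "u_bcs_good": utils.u_bcs_good,
            "u_bcs_poor": utils.u_bcs_poor,
            "u_mst_only": utils.u_mst_only,
            "u_mst_recon": utils.u_mst_recon,
            "p_recon": utils.p_recon,
        },
        "threshold_analysis": {
            "benefit": benefit(utils),
            "harm": harm(utils),
            "threshold": thr,
        },
        "ratio_cutoffs": {"threshold_prob": cutoff_threshold, "by_location": cutoffs},
        "decision_grid": grid.to_dict(orient="records"),
    }

    if cohort is not None:
        predicted = [
            config.model.predict(TumorLocation(loc), float(r))
            for loc, r in zip(cohort["location"], cohort["ratio"])
        ]
        observed = list(cohort["cosmesis_label"])
        counts = confusion_at_threshold(predicted, observed, thr)
        report["cohort_evaluation"] = {
            "n": len(cohort),
            "auc": auc(predicted, observed),
            "confusion": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
            "ppv": counts.ppv,
            "npv": counts.npv,
            "prevalence_good": observed.count("good") / len(observed),
        }

    psa = run_psa(
        utils=utils,
        ses=dict(config.psa_standard_errors),
        presentation=config.reference_patient,
        model=config.model,
        n=config.psa_n,
        seed=config.psa_seed,
    )
    report["psa"] = psa.summary()
    return report


def render_report_text(report: dict) -> str:
    """Human-readable rendering of :func:`run_full_report` output."""
    lines = ["Decision-model report (study defaults — validate before clinical use)", ""]
    coef = report["model"]["coefficients"]
    lines.append(f"Model ({report['model']['provenance']}):")
    for k, v in coef.items():
        lines.append(f"  {k:>24s} = {v: .6f}")
    t = report["threshold_analysis"]
    lines += [
        "",
        f"Benefit (BCS good vs pooled MST):  {t['benefit']:.3f}",
        f"Harm   (pooled MST vs BCS poor):   {t['harm']:.3f}",
        f"Treatment threshold:               {t['threshold']:.4f} "
        f"({100 * t['threshold']:.1f}%)",
        "",
        f"Ratio cut-offs at P = {report['ratio_cutoffs']['threshold_prob']}:",
    ]
    for loc, r in report["ratio_cutoffs"]["by_location"].items():
        lines.append(f"  {loc:>16s}: {r:6.1f}")
    if "cohort_evaluation" in report:
        ce = report["cohort_evaluation"]
        ppv = "undefined" if ce["ppv"] is None else f"{ce['ppv']:.3f}"
        npv = "undefined" if ce["npv"] is None else f"{ce['npv']:.3f}"
        lines += [
            "",
            f"Cohort (n = {ce['n']}): AUC {ce['auc']:.3f}, "
            f"TP {ce['confusion']['tp']} FP {ce['confusion']['fp']} "
            f"TN {ce['confusion']['tn']} FN {ce['confusion']['fn']}, "
            f"PPV {ppv}, NPV {npv}, prevalence {ce['prevalence_good']:.3f}",
        ]
    p = report["psa"]
    lines += [
        "",
        f"PSA (n = {p['n_samples']}, seed {p['seed']}): "
        f"P(BCS optimal) = {p['p_bcs_optimal']:.3f}, EVPI = {p['evpi']:.4f} "
        f"(baseline {p['baseline']})",
    ]
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
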