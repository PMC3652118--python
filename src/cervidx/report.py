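"""Diagnosis orchestration and JSON report serialization.

A full diagnosis ties the three phases together: the clinical record is
scored on the risk model, the cytology image is reduced to its feature
vector, and both feed the injury-resolution model.  The report is
JSON-first and deterministic for fixed inputs and configuration: it embeds
the package version, a hash of the effective model configuration, and
fingerprints of the inputs, so re-running reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Mapping

import numpy as np

from . import __version__
from .fuzzy import MamdaniModel, model_to_dict
from .imaging import FeatureVector, PipelineParams, extract_features
from .injury import InjuryResult, build_injury_model, resolve_injury
from .risk import ClinicalRecord, RiskResult, assess_risk, build_risk_model

__all__ = ["config_hash", "diagnose", "report_to_json", "render_text_report"]


def config_hash(*models: MamdaniModel, params: PipelineParams | None = None) -> str:
    """Stable SHA-256 over the effective model/pipeline configuration."""
    payload = {
        "models": [model_to_dict(m) for m in models],
        "pipeline": asdict(params) if params is not None else None,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _fingerprint_image(image: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(image).tobytes()).hexdigest()


def _fingerprint_record(record: ClinicalRecord) -> str:
    return hashlib.sha256(
        json.dumps(asdict(record), sort_keys=True).encode()
    ).hexdigest()


def diagnose(
    record: ClinicalRecord,
    image: np.ndarray,
    risk_model: MamdaniModel | None = None,
    injury_model: MamdaniModel | None = None,
    params: PipelineParams | None = None,
) -> dict:
    """Run the end-to-end diagnosis and return the report as a dict."""
    risk_model = risk_model or build_risk_model()
    injury_model = injury_model or build_injury_model()
    params = params or PipelineParams()

    risk = assess_risk(record, risk_model)
    features, regions, _ = extract_features(image, params)
    injury = resolve_injury(features, risk, injury_model)
    return build_report(record, image, risk, features, injury,
                        risk_model, injury_model, params)


def build_report(
    record: ClinicalRecord,
    image: np.ndarray,
    risk: RiskResult,
    features: FeatureVector,
    injury: InjuryResult,
    risk_model: MamdaniModel,
    injury_model: MamdaniModel,
    params: PipelineParams,
) -> dict:
    return {
        "risk": {
            "score": risk.score,
            "label": risk.label,
            "n_rules_fired": risk.n_fired,
        },
        "features": features.as_dict(),
        "injury": {
            "score": injury.score,
            "label": injury.label,
        },
        "provenance": {
            "injury_rules_fired": [
                {"if": dict(rule.antecedent), "then": rule.consequent,
                 "activation": act}
                for rule, act in injury.fired
            ],
            "record_sha256": _fingerprint_record(record),
            "image_sha256": _fingerprint_image(image),
        },
        "config_hash": config_hash(risk_model, injury_model, params=params),
        "versions": {"cervidx": __version__},
    }


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


_LABEL_TEXT = {
    "normal": "Normal (no alterations)",
    "agc": "AGC (atypical glandular cells)",
    "positive": "Positive to malignity",
}


def render_text_report(report: Mapping) -> str:
    """Human-readable rendering of the JSON report (never a separate
    computation)."""
    f = report["features"]
    lines = [
        "== Background evaluation ==",
        f"  risk score: {report['risk']['score']:.3f}  ->  {report['risk']['label']}",
        "== Image data ==",
        f"  mean nucleus area (dn): {f['dn']:.1f} px",
        f"  mean staining     (tn): {f['tn']:.1f}",
        f"  mean eccentricity (hn): {f['hn']:.3f}",
        f"  nucleolus count   (pn): {f['pn']}",
        f"  nuclei detected      : {f['n_nuclei']}",
        "== Injury resolution ==",
        f"  score: {report['injury']['score']:.2f} / 100",
        f"  call : {_LABEL_TEXT.get(report['injury']['label'], report['injury']['label'])}",
    ]
    return "\n".join(lines)
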