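"""Injury-resolution model (phase 3).

Fuses the four morphometric image features (mean nucleus area, mean
staining, mean eccentricity, total nucleolus count) with the crisp clinical
risk score into a three-way call on a 0-100 scale: Normal, AGC (atypical
glandular cells), or Positive-to-malignity.

As with the risk model, only five of the 108 validated rules were
published; the remainder are generated by a documented, non-clinical
severity policy pinned to those five rows.  Combinations pairing dark
staining with detected nucleoli are disabled: in a hyperchromatic (dark)
nucleus the nucleolus cannot be resolved, so such rules are physically
meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .fuzzy import (
    ConfigurationError,
    MamdaniModel,
    Rule,
    enumerate_rule_space,
    infer,
    model_from_dict,
)
from .imaging import FeatureVector
from .risk import RiskResult, _check_against_fixture

logger = logging.getLogger(__name__)

__all__ = [
    "InjuryResult",
    "InjurySeverityPolicy",
    "build_injury_model",
    "generate_injury_rules",
    "load_printed_injury_rules",
    "resolve_injury",
    "classify_score",
]


def _load_config(name: str) -> dict:
    text = resources.files("cervidx.configs").joinpath(name).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class InjuryResult:
    """Crisp lesion score in [0, 100], its label, and rule provenance."""

    score: float
    label: str                      # "normal" | "agc" | "positive"
    activations: Mapping[str, float]
    fired: tuple                    # (rule, activation) pairs with activation > 0


@dataclass(frozen=True)
class InjurySeverityPolicy:
    """Non-clinical scoring heuristic for the unpublished rule base.

    Malignancy points per antecedent label; the published example rows pin
    the thresholds (small/dark/regular/no-nucleoli/negative must still map
    to Normal, so dark staining plus absent nucleoli stays below the AGC
    band on its own).
    """

    area_points: Mapping[str, int] = None        # type: ignore[assignment]
    staining_points: Mapping[str, int] = None    # type: ignore[assignment]
    eccentricity_points: Mapping[str, int] = None  # type: ignore[assignment]
    nucleoli_points: Mapping[str, int] = None    # type: ignore[assignment]
    risk_points: Mapping[str, int] = None        # type: ignore[assignment]
    agc_threshold: int = 4
    positive_threshold: int = 6

    def __post_init__(self):
        defaults = {
            "area_points": {"small": 0, "medium": 1, "large": 3},
            "staining_points": {"clear": 0, "media": 1, "dark": 2},
            "eccentricity_points": {"regular": 0, "irregular": 3},
            "nucleoli_points": {"null": 1, "few": 0, "many": 3},
            "risk_points": {"negative": 0, "positive": 2},
        }
        for name, default in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, default)

    def points(self, antecedent: Mapping[str, str]) -> int:
        return (
            self.area_points[antecedent["nucleus_area"]]
            + self.staining_points[antecedent["staining"]]
            + self.eccentricity_points[antecedent["eccentricity"]]
            + self.nucleoli_points[antecedent["nucleoli"]]
            + self.risk_points[antecedent["risk"]]
        )

    def consequent(self, antecedent: Mapping[str, str]) -> str:
        pts = self.points(antecedent)
        if pts >= self.positive_threshold:
            return "positive"
        if pts >= self.agc_threshold:
            return "agc"
        return "normal"

    def is_invalid(self, antecedent: Mapping[str, str]) -> bool:
        # nucleoli are not resolvable inside a hyperchromatic nucleus
        return antecedent["staining"] == "dark" and antecedent["nucleoli"] in (
            "few", "many",
        )


def load_printed_injury_rules() -> list[Rule]:
    cfg = _load_config("injury_rules_printed.yaml")
    return [Rule(r["if"], r["then"]) for r in cfg["rules"]]


def generate_injury_rules(
    model: MamdaniModel,
    policy: InjurySeverityPolicy | None = None,
) -> list[Rule]:
    """Assign all 108 consequents from the policy; disable the physically
    invalid dark-staining-with-nucleoli combinations; verify the printed
    fixture."""
    policy = policy or InjurySeverityPolicy()
    rules = [
        Rule(ante, policy.consequent(ante), enabled=not policy.is_invalid(ante))
        for ante in enumerate_rule_space(model)
    ]
    _check_against_fixture(model, rules, load_printed_injury_rules(), "injury")
    return rules


def build_injury_model(
    config: Mapping | None = None,
    policy: InjurySeverityPolicy | None = None,
) -> MamdaniModel:
    """Build the injury-resolution model from the shipped (or a custom)
    definition, generating the rule base when none is supplied."""
    cfg = dict(config) if config is not None else _load_config("injury_variables.yaml")
    model = model_from_dict(cfg)
    if not model.rules:
        model = model.replace_rules(generate_injury_rules(model, policy))
    return model


def classify_score(score: float, model: MamdaniModel | None = None) -> str:
    """Label with maximal lesion-set membership at ``score``; the more
    severe label wins ties (the overlap bands split at their crossings)."""
    model = model or build_injury_model()
    from .fuzzy import classify_value

    return classify_value(model.output, float(score))


def resolve_injury(
    features: FeatureVector,
    risk: RiskResult | float,
    model: MamdaniModel | None = None,
) -> InjuryResult:
    """Run the fused diagnosis on image features plus a risk score."""
    if features.n_nuclei < 1:
        raise ConfigurationError("feature vector with no nuclei cannot be scored")
    model = model or build_injury_model()
    risk_score = risk.score if isinstance(risk, RiskResult) else float(risk)
    result = infer(
        model,
        {
            "nucleus_area": features.dn,
            "staining": features.tn,
            "eccentricity": features.hn,
            "nucleoli": float(features.pn),
            "risk": risk_score,
        },
    )
    return InjuryResult(
        score=result.value,
        label=result.label,
        activations=dict(result.activations),
        fired=result.fired,
    )
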