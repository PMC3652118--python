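"""Clinical-background risk model (phase 1).

Seven fields from a patient's gynecological record — age, onset of sexual
activity, number of sexual partners, number of pregnancies, age at first
pregnancy, STD history, and cervical lesions on exploration — feed a
Mamdani model whose output is a crisp risk score with a Negative/Positive
label.

The published system validated 360 of the 972 possible rules with
specialists but printed only twenty of them.  This module therefore ships
(a) those twenty rows as a locked fixture and (b) a documented, clearly
non-clinical severity-scoring policy that assigns a consequent to every
combination, constrained at build time to agree with the fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .fuzzy import (
    ConfigurationError,
    FuzzyVariable,
    InputError,
    MamdaniModel,
    Rule,
    enumerate_rule_space,
    infer,
    model_from_dict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "RiskResult",
    "RiskSeverityPolicy",
    "build_risk_model",
    "generate_default_rules",
    "load_printed_risk_rules",
    "assess_risk",
]

_AGE_ORDER = ("young", "adult", "mature")


def _load_config(name: str) -> dict:
    text = resources.files("cervidx.configs").joinpath(name).read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's risk inputs.

    ``pg`` (age at first pregnancy, years) may be ``None`` only for
    nulliparous records (``ng == 0``); it is then imputed as the midpoint of
    the first-pregnancy universe at inference time, where the "null"
    pregnancy set dominates anyway.
    """

    age: float
    ivsa: float          # onset of sexual activity, years
    ps: float            # number of sexual partners
    ng: float            # number of pregnancies
    pg: float | None     # age at first pregnancy, years
    ets: bool            # STD history
    le: bool             # cervical lesions found on exploration

    def validate(self) -> None:
        if self.age < 0 or self.ivsa < 0 or self.ps < 0 or self.ng < 0:
            raise InputError(f"record has negative fields: {self}")
        if self.age < self.ivsa:
            raise InputError(
                f"age ({self.age}) precedes onset of sexual activity ({self.ivsa})"
            )
        if self.ng > 0:
            if self.pg is None:
                raise InputError("record with pregnancies lacks age at first pregnancy")
            if self.pg < self.ivsa:
                raise InputError(
                    f"first pregnancy age ({self.pg}) precedes onset of sexual "
                    f"activity ({self.ivsa})"
                )

    @classmethod
    def from_mapping(cls, m: Mapping) -> "ClinicalRecord":
        def as_bool(v):
            if isinstance(v, bool):
                return v
            if isinstance(v, (int, float)):
                return bool(v)
            return str(v).strip().lower() in ("1", "true", "yes", "y")

        pg = m.get("pg")
        if pg in (None, "", "na", "NA", "-", "—") or (
            isinstance(pg, float) and pg != pg  # NaN from empty CSV cells
        ):
            pg = None
        try:
            rec = cls(
                age=float(m["age"]),
                ivsa=float(m["ivsa"]),
                ps=float(m["ps"]),
                ng=float(m["ng"]),
                pg=None if pg is None else float(pg),
                ets=as_bool(m.get("ets", False)),
                le=as_bool(m.get("le", False)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed clinical record {dict(m)!r}: {exc}") from exc
        rec.validate()
        return rec


@dataclass(frozen=True)
class RiskResult:
    """Crisp risk score on the model's output universe plus its label."""

    score: float
    label: str           # "negative" | "positive"
    activations: Mapping[str, float]
    n_fired: int


# ---------------------------------------------------------------------------
# Rule generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskSeverityPolicy:
    """Non-clinical scoring heuristic that fills the unpublished rule base.

    Each antecedent combination receives risk points for its high-risk
    memberships; the consequent is Positive when the total reaches
    ``threshold``.  The published example rows pin the weights: with few
    partners even STD history plus visible lesions stays Negative, while
    many partners alone is Positive.

    Combinations whose sexual-onset age bracket is older than the current
    age bracket are physically impossible and flagged disabled.
    """

    partners_points: Mapping[str, int] = None  # type: ignore[assignment]
    pregnancies_many_points: int = 3
    young_first_pregnancy_bonus: int = 1       # only with many pregnancies
    std_points: int = 1
    lesion_points: int = 1
    threshold: int = 3

    def __post_init__(self):
        if self.partners_points is None:
            object.__setattr__(
                self, "partners_points", {"few": 0, "many": 3, "unusual": 4}
            )

    def points(self, antecedent: Mapping[str, str]) -> int:
        pts = self.partners_points.get(antecedent["partners"], 0)
        if antecedent["pregnancies"] == "many":
            pts += self.pregnancies_many_points
            if antecedent["first_pregnancy_age"] == "young":
                pts += self.young_first_pregnancy_bonus
        if antecedent["std_history"] == "yes":
            pts += self.std_points
        if antecedent["lesions"] == "yes":
            pts += self.lesion_points
        return pts

    def consequent(self, antecedent: Mapping[str, str]) -> str:
        return "positive" if self.points(antecedent) >= self.threshold else "negative"

    def is_invalid(self, antecedent: Mapping[str, str]) -> bool:
        age_i = _AGE_ORDER.index(antecedent["age"])
        onset_i = _AGE_ORDER.index(antecedent["sexual_onset"])
        return onset_i > age_i


def load_printed_risk_rules() -> list[Rule]:
    """The twenty published rule rows, as shipped (synonyms unresolved)."""
    cfg = _load_config("risk_rules_printed.yaml")
    return [Rule(r["if"], r["then"]) for r in cfg["rules"]]


def generate_default_rules(
    model: MamdaniModel,
    policy: RiskSeverityPolicy | None = None,
) -> list[Rule]:
    """Assign a consequent to every antecedent combination via ``policy``.

    Impossible combinations keep their policy consequent but are disabled.
    The result is checked against the printed fixture; any disagreement
    raises a configuration error naming the offending row.
    """
    policy = policy or RiskSeverityPolicy()
    rules = [
        Rule(ante, policy.consequent(ante), enabled=not policy.is_invalid(ante))
        for ante in enumerate_rule_space(model)
    ]
    _check_against_fixture(model, rules, load_printed_risk_rules(), "risk")
    return rules


def _check_against_fixture(
    model: MamdaniModel,
    generated: Iterable[Rule],
    fixture: Iterable[Rule],
    name: str,
) -> None:
    def canon(rule: Rule) -> tuple:
        ante = tuple(
            model.input_by_name(v).canonical(lbl)
            for v, lbl in sorted(rule.antecedent.items())
        )
        return ante

    by_ante = {canon(r): model.output.canonical(r.consequent) for r in generated}
    for i, row in enumerate(fixture, start=1):
        key = canon(row)
        want = model.output.canonical(row.consequent)
        got = by_ante.get(key)
        if got != want:
            raise ConfigurationError(
                f"{name} severity policy contradicts printed rule row {i}: "
                f"{dict(row.antecedent)} -> expected {want!r}, generated {got!r}"
            )


# ---------------------------------------------------------------------------
# Model construction and assessment
# ---------------------------------------------------------------------------


def build_risk_model(
    config: Mapping | None = None,
    policy: RiskSeverityPolicy | None = None,
    output_preset: str | None = None,
) -> MamdaniModel:
    """Build the risk model from the shipped (or a custom) definition.

    ``output_preset="narrow"`` selects the alternative narrow risk-output
    universe; the default output universe is the one the injury model
    consumes directly.  When the definition carries no rules, the full base
    is generated from the severity policy and verified against the printed
    fixture.
    """
    cfg = dict(config) if config is not None else _load_config("risk_variables.yaml")
    if output_preset:
        presets = cfg.get("output_presets", {})
        if output_preset not in presets:
            raise ConfigurationError(
                f"unknown risk output preset {output_preset!r} "
                f"(available: {sorted(presets)})"
            )
        cfg = {**cfg, "output": presets[output_preset]}
    model = model_from_dict(cfg)
    if not model.rules:
        model = model.replace_rules(generate_default_rules(model, policy))
    return model


def record_to_inputs(record: ClinicalRecord, model: MamdaniModel) -> dict[str, float]:
    """Map a validated record onto the model's crisp input variables."""
    record.validate()
    pg = record.pg
    if pg is None:
        var: FuzzyVariable = model.input_by_name("first_pregnancy_age")
        pg = 0.5 * (var.universe[0] + var.universe[1])
        logger.info(
            "nulliparous record: first pregnancy age imputed as universe midpoint %g",
            pg,
        )
    return {
        "age": record.age,
        "sexual_onset": record.ivsa,
        "partners": record.ps,
        "pregnancies": record.ng,
        "first_pregnancy_age": pg,
        "std_history": 1.0 if record.ets else 0.0,
        "lesions": 1.0 if record.le else 0.0,
    }


def assess_risk(record: ClinicalRecord, model: MamdaniModel | None = None) -> RiskResult:
    """Score one patient record on the risk model."""
    model = model or build_risk_model()
    result = infer(model, record_to_inputs(record, model))
    return RiskResult(
        score=result.value,
        label=result.label,
        activations=dict(result.activations),
        n_fired=len(result.fired),
    )
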