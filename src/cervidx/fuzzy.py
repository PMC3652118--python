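"""Generic Mamdani fuzzy-inference engine.

The engine covers the classic Mamdani controller cycle: piecewise-linear
(triangle / trapezoid) membership functions, fuzzification of crisp inputs,
rule firing with a t-norm AND, min-implication (clipping), max-aggregation
of the consequent sets, and centroid (centre-of-gravity) defuzzification.

Models are plain dataclasses and can be loaded from / dumped to a small
declarative YAML/JSON schema (see :func:`model_from_dict`), so that a
complete inference system — variables, rule base, engine options — is data,
not code.

Numerical note on the centroid: the aggregated output surface
``max_s min(act_s, mu_s(x))`` is piecewise linear, so its centroid has a
segment-wise closed form.  The default defuzzifier evaluates that closed
form exactly (resolution-independent, reproducible to machine precision);
a uniform-grid sampled variant is available through
``EngineOptions.defuzz_mode = "sampled"``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "InputError",
    "NoRuleFiredError",
    "FuzzySet",
    "FuzzyVariable",
    "Rule",
    "EngineOptions",
    "MamdaniModel",
    "InferenceResult",
    "membership",
    "fuzzify",
    "fire_rule",
    "defuzzify_centroid",
    "classify_value",
    "infer",
    "enumerate_rule_space",
    "model_from_dict",
    "model_to_dict",
    "load_model",
    "save_model",
]


class ConfigurationError(ValueError):
    """A model definition violates the schema or its invariants."""


class InputError(ValueError):
    """A crisp input or record is malformed."""


class NoRuleFiredError(RuntimeError):
    """No rule produced a positive activation for the given inputs."""

    def __init__(self, message: str, inputs=None, fuzzified=None):
        super().__init__(message)
        self.inputs = inputs
        self.fuzzified = fuzzified


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzySet:
    """One linguistic set with a triangle or trapezoid membership function.

    ``params`` are the ordered universe breakpoints: ``(a, b, c)`` for a
    triangle (apex at ``b``) or ``(a, b, c, d)`` for a trapezoid (plateau on
    ``[b, c]``).  Degenerate edges (``a == b`` or ``c == d``) give vertical
    shoulders, e.g. the boolean-style triangle ``(0 0 0.5)`` whose membership
    is 1 at 0.
    """

    label: str
    shape: str
    params: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.shape not in ("triangle", "trapezoid"):
            raise ConfigurationError(
                f"set {self.label!r}: unknown shape {self.shape!r}"
            )
        n = 3 if self.shape == "triangle" else 4
        if len(self.params) != n:
            raise ConfigurationError(
                f"set {self.label!r}: {self.shape} needs {n} breakpoints, "
                f"got {len(self.params)}"
            )
        if any(p2 < p1 for p1, p2 in zip(self.params, self.params[1:])):
            raise ConfigurationError(
                f"set {self.label!r}: breakpoints must be non-decreasing, "
                f"got {self.params}"
            )

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        """Always as ``(a, b, c, d)``; a triangle has ``b == c``."""
        if self.shape == "triangle":
            a, b, c = self.params
            return (a, b, b, c)
        return self.params  # type: ignore[return-value]

    @property
    def support(self) -> tuple[float, float]:
        bp = self.breakpoints
        return (bp[0], bp[3])

    def membership(self, x):
        """Membership degree of ``x`` (scalar or array) in this set."""
        a, b, c, d = self.breakpoints
        xs = np.asarray(x, dtype=float)
        out = np.zeros(xs.shape)
        if b > a:
            rising = (xs - a) / (b - a)
            out = np.where((xs >= a) & (xs < b), rising, out)
        if d > c:
            falling = (d - xs) / (d - c)
            out = np.where((xs > c) & (xs <= d), falling, out)
        out = np.where((xs >= b) & (xs <= c), 1.0, out)
        if np.isscalar(x) or xs.ndim == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class FuzzyVariable:
    """A linguistic variable: a universe of discourse and its ordered sets.

    ``aliases`` maps synonym labels (as printed in rule tables) onto the
    canonical set labels, e.g. ``little -> few`` or ``not common -> unusual``.
    """

    name: str
    universe: tuple[float, float]
    sets: tuple[FuzzySet, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "universe", tuple(float(u) for u in self.universe))
        object.__setattr__(self, "sets", tuple(self.sets))
        lo, hi = self.universe
        if lo >= hi:
            raise ConfigurationError(f"variable {self.name!r}: empty universe")
        if not self.sets:
            raise ConfigurationError(f"variable {self.name!r}: needs at least one set")
        for s in self.sets:
            slo, shi = s.support
            if slo < lo - 1e-9 or shi > hi + 1e-9:
                raise ConfigurationError(
                    f"variable {self.name!r}: set {s.label!r} support "
                    f"{s.support} outside universe {self.universe}"
                )
        object.__setattr__(
            self, "aliases", {k.lower(): v.lower() for k, v in dict(self.aliases).items()}
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sets)

    def canonical(self, label: str) -> str:
        """Resolve a (possibly synonym) label to the canonical set label."""
        key = label.strip().lower()
        key = self.aliases.get(key, key)
        if key not in self.labels:
            raise ConfigurationError(
                f"variable {self.name!r}: unknown set label {label!r} "
                f"(known: {self.labels})"
            )
        return key

    def set_by_label(self, label: str) -> FuzzySet:
        key = self.canonical(label)
        return next(s for s in self.sets if s.label == key)

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        if x < lo or x > hi:
            logger.warning(
                "variable %s: input %g outside universe [%g, %g]; clamped",
                self.name, x, lo, hi,
            )
            return min(max(x, lo), hi)
        return x

    def snap_to_support(self, x: float) -> float:
        """Move ``x`` to the nearest support boundary of any set.

        The printed interval tables contain hairline coverage gaps (e.g.
        between ``(0 0 0.5)`` and ``(0.51 4 8)``); a value falling in such a
        gap has zero membership everywhere and is snapped to the closest
        support edge so inference can proceed.
        """
        edges = [e for s in self.sets for e in s.support]
        nearest = min(edges, key=lambda e: abs(e - x))
        logger.warning(
            "variable %s: value %g lies in a membership gap; snapped to %g",
            self.name, x, nearest,
        )
        return nearest


@dataclass(frozen=True)
class Rule:
    """One inference rule: antecedent labels per input variable -> output label."""

    antecedent: Mapping[str, str]
    consequent: str
    enabled: bool = True

    def __post_init__(self):
        object.__setattr__(self, "antecedent", dict(self.antecedent))


@dataclass(frozen=True)
class EngineOptions:
    """Mamdani engine operators; the defaults are the classic controller's."""

    and_op: str = "min"          # t-norm over antecedent degrees: min | product
    implication: str = "min"     # consequent clipping
    aggregation: str = "max"     # s-norm over rule outputs
    defuzz: str = "centroid"
    defuzz_mode: str = "exact"   # exact | sampled
    resolution: int = 1001       # grid size for sampled mode

    def __post_init__(self):
        if self.and_op not in ("min", "product"):
            raise ConfigurationError(f"unknown AND operator {self.and_op!r}")
        if self.implication != "min" or self.aggregation != "max":
            raise ConfigurationError("only min-implication / max-aggregation supported")
        if self.defuzz != "centroid":
            raise ConfigurationError("only centroid defuzzification supported")
        if self.defuzz_mode not in ("exact", "sampled"):
            raise ConfigurationError(f"unknown defuzz mode {self.defuzz_mode!r}")
        if self.resolution < 3:
            raise ConfigurationError("resolution must be >= 3")


@dataclass(frozen=True)
class MamdaniModel:
    name: str
    inputs: tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: tuple[Rule, ...]
    options: EngineOptions = field(default_factory=EngineOptions)

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self._normalize_rules()))

    def _normalize_rules(self) -> list[Rule]:
        by_name = {v.name: v for v in self.inputs}
        normalized = []
        for i, r in enumerate(self.rules):
            ante = {}
            for var_name, label in r.antecedent.items():
                if var_name not in by_name:
                    raise ConfigurationError(
                        f"model {self.name!r}, rule {i}: unknown input variable "
                        f"{var_name!r}"
                    )
                ante[var_name] = by_name[var_name].canonical(label)
            cons = self.output.canonical(r.consequent)
            normalized.append(Rule(ante, cons, r.enabled))
        return normalized

    def input_by_name(self, name: str) -> FuzzyVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise InputError(f"model {self.name!r}: no input variable {name!r}")

    def replace_rules(self, rules: Iterable[Rule]) -> "MamdaniModel":
        return replace(self, rules=tuple(rules))


@dataclass(frozen=True)
class InferenceResult:
    """Crisp output plus provenance of the inference."""

    value: float
    label: str
    activations: Mapping[str, float]
    fired: tuple[tuple[Rule, float], ...]
    fuzzified: Mapping[str, Mapping[str, float]]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def membership(fset: FuzzySet, x: float) -> float:
    """Membership degree of crisp ``x`` in ``fset`` (piecewise linear)."""
    if not np.isfinite(x):
        raise InputError(f"membership: x must be finite, got {x!r}")
    return fset.membership(float(x))


def fuzzify(variable: FuzzyVariable, x: float, snap_gaps: bool = True) -> dict[str, float]:
    """Degrees of ``x`` in every set of ``variable`` (clamped to the universe).

    If every set gives 0 and ``snap_gaps`` is true, ``x`` is snapped to the
    nearest support boundary (the printed tables have hairline gaps).
    """
    if not np.isfinite(x):
        raise InputError(f"fuzzify({variable.name}): x must be finite, got {x!r}")
    x = variable.clamp(float(x))
    degrees = {s.label: s.membership(x) for s in variable.sets}
    if snap_gaps and all(d == 0.0 for d in degrees.values()):
        x = variable.snap_to_support(x)
        degrees = {s.label: s.membership(x) for s in variable.sets}
        if all(d == 0.0 for d in degrees.values()):
            # the support edge itself can be open (membership 0); fall back
            # to full membership of the set whose plateau is closest
            nearest = _nearest_plateau_set(variable, x)
            degrees[nearest.label] = 1.0
    return degrees


def _nearest_plateau_set(variable: FuzzyVariable, x: float) -> FuzzySet:
    def key(item):
        i, s = item
        _, b, c, _ = s.breakpoints
        # ties go to the higher-indexed (more severe) set
        return (max(b - x, 0.0, x - c), -i)

    return min(enumerate(variable.sets), key=key)[1]


def fire_rule(
    rule: Rule,
    degrees: Mapping[str, Mapping[str, float]],
    and_op: str = "min",
) -> float:
    """Activation of one rule given per-variable fuzzified degree maps."""
    if not rule.enabled:
        return 0.0
    acts = []
    for var_name, label in rule.antecedent.items():
        if var_name not in degrees:
            raise InputError(f"fire_rule: no degrees supplied for variable {var_name!r}")
        var_degrees = degrees[var_name]
        if label not in var_degrees:
            raise InputError(
                f"fire_rule: variable {var_name!r} has no degree for label {label!r}"
            )
        acts.append(var_degrees[label])
    if not acts:
        return 0.0
    if and_op == "product":
        return float(np.prod(acts))
    return float(min(acts))


def _clipped_breakpoints(fset: FuzzySet, act: float) -> list[float]:
    """Universe abscissae where ``min(act, mu(x))`` changes slope."""
    a, b, c, d = fset.breakpoints
    pts = [a, b, c, d]
    if 0.0 < act < 1.0:
        if b > a:
            pts.append(a + act * (b - a))
        if d > c:
            pts.append(d - act * (d - c))
    return pts


def _aggregate_on_grid(active, grid):
    agg = np.zeros_like(grid)
    for fset, act in active:
        np.maximum(agg, np.minimum(act, fset.membership(grid)), out=agg)
    return agg


def defuzzify_centroid(
    output: FuzzyVariable,
    activations: Mapping[str, float],
    options: EngineOptions | None = None,
) -> float:
    """Centroid of the min-clipped, max-aggregated output surface.

    Raises :class:`NoRuleFiredError` when every activation is zero.
    """
    options = options or EngineOptions()
    active = [
        (output.set_by_label(label), min(1.0, float(act)))
        for label, act in activations.items()
        if act > 0.0
    ]
    if not active:
        raise NoRuleFiredError(
            f"defuzzify({output.name}): all activations are zero",
            inputs=dict(activations),
        )
    lo, hi = output.universe

    if options.defuzz_mode == "sampled":
        grid = np.linspace(lo, hi, options.resolution)
        agg = _aggregate_on_grid(active, grid)
        den = np.trapezoid(agg, grid)
        if den <= 0:
            raise NoRuleFiredError(
                f"defuzzify({output.name}): aggregated surface has zero area",
                inputs=dict(activations),
            )
        return float(np.trapezoid(grid * agg, grid) / den)

    # Exact mode: the aggregate is piecewise linear.  Collect every abscissa
    # where any clipped set changes slope; inside each open cell every
    # clipped set is one linear piece, which we fit from two interior points
    # (endpoint values are unusable where a vertical edge sits on a knot).
    # Adding pairwise crossings makes the max a single linear piece per cell.
    pts = {lo, hi}
    for fset, act in active:
        pts.update(p for p in _clipped_breakpoints(fset, act) if lo <= p <= hi)
    knots = sorted(pts)

    area = 0.0
    moment = 0.0
    for x0, x1 in zip(knots, knots[1:]):
        h = x1 - x0
        if h <= 0:
            continue
        q1, q2 = x0 + h / 3.0, x0 + 2.0 * h / 3.0
        lines = []
        for fset, act in active:
            f1 = min(act, fset.membership(q1))
            f2 = min(act, fset.membership(q2))
            slope = (f2 - f1) / (q2 - q1)
            lines.append((slope, f1 - slope * q1))
        xs = {x0, x1}
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                mi, bi = lines[i]
                mj, bj = lines[j]
                if mi != mj:
                    xc = (bj - bi) / (mi - mj)
                    if x0 < xc < x1:
                        xs.add(xc)
        cell = sorted(xs)
        for u0, u1 in zip(cell, cell[1:]):
            hu = u1 - u0
            if hu <= 0:
                continue
            f0 = max(m * u0 + b for m, b in lines)
            f1v = max(m * u1 + b for m, b in lines)
            area += 0.5 * (f0 + f1v) * hu
            # integral of x * linear(f) over [u0, u1]
            moment += hu / 6.0 * (f0 * (2.0 * u0 + u1) + f1v * (u0 + 2.0 * u1))
    if area <= 0:
        raise NoRuleFiredError(
            f"defuzzify({output.name}): aggregated surface has zero area",
            inputs=dict(activations),
        )
    return moment / area


def classify_value(output: FuzzyVariable, x: float) -> str:
    """Output set with maximal membership at ``x``; ties go to the more
    severe (higher-indexed) set, and a value in a membership gap is snapped
    to the nearest support edge first."""
    degrees = [s.membership(x) for s in output.sets]
    if all(d == 0.0 for d in degrees):
        x = output.snap_to_support(x)
        degrees = [s.membership(x) for s in output.sets]
    if all(d == 0.0 for d in degrees):
        nearest = _nearest_plateau_set(output, x)
        return nearest.label
    best = max(degrees)
    winner = max(i for i, d in enumerate(degrees) if d >= best - 1e-12)
    return output.sets[winner].label


def infer(model: MamdaniModel, inputs: Mapping[str, float]) -> InferenceResult:
    """Run the full Mamdani cycle on crisp inputs.

    Returns the crisp output, the winning output label, and provenance
    (per-label aggregated activations and every rule that fired).
    """
    missing = [v.name for v in model.inputs if v.name not in inputs]
    if missing:
        raise InputError(f"model {model.name!r}: missing inputs {missing}")
    degrees = {v.name: fuzzify(v, inputs[v.name]) for v in model.inputs}

    activations: dict[str, float] = {}
    fired: list[tuple[Rule, float]] = []
    for rule in model.rules:
        act = fire_rule(rule, degrees, model.options.and_op)
        if act > 0.0:
            fired.append((rule, act))
            prev = activations.get(rule.consequent, 0.0)
            activations[rule.consequent] = max(prev, act)
    if not activations:
        raise NoRuleFiredError(
            f"model {model.name!r}: no rule fired",
            inputs=dict(inputs),
            fuzzified=degrees,
        )
    value = defuzzify_centroid(model.output, activations, model.options)
    label = classify_value(model.output, value)
    return InferenceResult(value, label, activations, tuple(fired), degrees)


def enumerate_rule_space(model: MamdaniModel) -> list[dict[str, str]]:
    """Every antecedent combination, once, in lexicographic label order
    (per-variable set order as declared)."""
    names = [v.name for v in model.inputs]
    label_lists = [v.labels for v in model.inputs]
    return [
        dict(zip(names, combo)) for combo in itertools.product(*label_lists)
    ]


# ---------------------------------------------------------------------------
# Declarative configuration
# ---------------------------------------------------------------------------


def _variable_from_dict(d: Mapping) -> FuzzyVariable:
    try:
        sets = tuple(
            FuzzySet(s["label"].lower(), s["shape"], tuple(s["params"]))
            for s in d["sets"]
        )
        return FuzzyVariable(
            name=d["name"],
            universe=tuple(d["universe"]),
            sets=sets,
            aliases=d.get("aliases", {}),
        )
    except KeyError as exc:
        raise ConfigurationError(f"variable definition missing key {exc}") from exc


def _variable_to_dict(v: FuzzyVariable) -> dict:
    return {
        "name": v.name,
        "universe": list(v.universe),
        "sets": [
            {"label": s.label, "shape": s.shape, "params": list(s.params)}
            for s in v.sets
        ],
        **({"aliases": dict(v.aliases)} if v.aliases else {}),
    }


def model_from_dict(d: Mapping) -> MamdaniModel:
    """Build a model from the declarative schema (YAML/JSON-friendly)."""
    try:
        inputs = tuple(_variable_from_dict(v) for v in d["inputs"])
        output = _variable_from_dict(d["output"])
    except (TypeError, KeyError) as exc:
        raise ConfigurationError(f"malformed model definition: {exc}") from exc
    rules = tuple(
        Rule(r["if"], r["then"], bool(r.get("enabled", True)))
        for r in d.get("rules", [])
    )
    options = EngineOptions(**d.get("engine", {}))
    return MamdaniModel(
        name=d.get("name", "model"),
        inputs=inputs,
        output=output,
        rules=rules,
        options=options,
    )


def model_to_dict(model: MamdaniModel) -> dict:
    return {
        "name": model.name,
        "inputs": [_variable_to_dict(v) for v in model.inputs],
        "output": _variable_to_dict(model.output),
        "rules": [
            {"if": dict(r.antecedent), "then": r.consequent, "enabled": r.enabled}
            for r in model.rules
        ],
        "engine": {
            "and_op": model.options.and_op,
            "implication": model.options.implication,
            "aggregation": model.options.aggregation,
            "defuzz": model.options.defuzz,
            "defuzz_mode": model.options.defuzz_mode,
            "resolution": model.options.resolution,
        },
    }


def load_model(path: str | Path) -> MamdaniModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model(model: MamdaniModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
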