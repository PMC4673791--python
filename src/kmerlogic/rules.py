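"""Decision-list rule models over k-mer frequency intervals.

A model is an ordered list of if-then rules plus a default class. Each rule
is a conjunction of literals; a literal constrains one k-mer's frequency
(or significance score) to a union of half-open intervals ``[lo, hi)``
where ``lo`` may be -inf and ``hi`` may be +inf. Learners only ever emit
single-interval literals; the union form exists so that published rule sets
containing a within-rule disjunction on one feature (equivalently, the
complement of an interval) can be represented as a single rule.

Prediction evaluates rules top to bottom and returns the conclusion of the
first rule whose literals all hold, falling back to the default class.

Models serialize to JSON and render to a human-readable text dialect in
which frequencies are scaled by 1e5 for readability, e.g.::

    H. pylori: 5.56<=f(GTAC)<42.82
    A. baumannii: f(GTAC)>=229.10 & f(TGCA)>=515.63
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError

INF = math.inf


@dataclass(frozen=True)
class Literal:
    """One condition: feature value lies in a union of half-open intervals."""

    feature: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValidationError("literal needs at least one interval")
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValidationError(f"empty interval [{lo}, {hi}) in literal")

    @classmethod
    def interval(cls, feature: str, lo: float = -INF, hi: float = INF) -> "Literal":
        return cls(feature=feature, intervals=((lo, hi),))

    @property
    def lo(self) -> float:
        """Lower bound (single-interval literals only)."""
        (interval,) = self.intervals
        return interval[0]

    @property
    def hi(self) -> float:
        (interval,) = self.intervals
        return interval[1]

    def matches(self, value: float) -> bool:
        return any(lo <= value < hi for lo, hi in self.intervals)


@dataclass
class Rule:
    """A conjunction of literals with a class conclusion.

    ``coverage`` is ``(positives, negatives)`` matched on the training set:
    samples the rule matches whose label is / is not the conclusion. A rule
    with zero literals matches everything.
    """

    literals: list[Literal]
    conclusion: str
    coverage: tuple[int, int] | None = None

    def matches(self, values: Mapping[str, float]) -> bool:
        for lit in self.literals:
            if lit.feature not in values:
                raise ValidationError(f"vector lacks feature {lit.feature!r}")
            if not lit.matches(values[lit.feature]):
                return False
        return True

    def features(self) -> set[str]:
        return {lit.feature for lit in self.literals}


@dataclass
class RuleModel:
    """Ordered decision list with a default class."""

    rules: list[Rule]
    default_class: str
    rank: str | None = None
    learner: str = "manual"
    params: dict = field(default_factory=dict)
    seed: int | None = None
    k: int | None = None

    def predict(self, vector) -> str:
        """Conclusion of the first matching rule, else the default class.

        ``vector`` may be a mapping from k-mer to value or a
        :class:`~kmerlogic.kmer_features.FrequencyVector`.
        """
        values = _as_mapping(vector)
        for rule in self.rules:
            if rule.matches(values):
                return rule.conclusion
        return self.default_class

    def predict_many(self, vectors: Iterable) -> list[str]:
        return [self.predict(v) for v in vectors]


class _VectorView(Mapping):
    """Read-through mapping over a FrequencyVector (absent k-mer -> 0.0)."""

    def __init__(self, fv) -> None:
        self._fv = fv

    def __getitem__(self, key: str) -> float:
        return self._fv.get(key)

    def __contains__(self, key: str) -> bool:
        return len(key) == self._fv.k and not (set(key) - set("ACGT"))

    def __iter__(self):
        return iter(self._fv.values)

    def __len__(self) -> int:
        return len(self._fv.values)


def _as_mapping(vector) -> Mapping[str, float]:
    if isinstance(vector, Mapping):
        return vector
    if hasattr(vector, "values") and hasattr(vector, "k"):
        return _VectorView(vector)
    raise ValidationError(f"cannot interpret {type(vector).__name__} as a feature vector")


def predict(model: RuleModel, vector) -> str:
    """Functional alias for :meth:`RuleModel.predict`."""
    return model.predict(vector)


def model_complexity(model: RuleModel) -> dict:
    """Size statistics of a model: rules, literals per rule, distinct k-mers.

    The default rule is not counted. An empty rule list reports 0 for the
    mean literal count.
    """
    n_rules = len(model.rules)
    n_literals = sum(len(r.literals) for r in model.rules)
    kmers = set()
    for r in model.rules:
        kmers |= r.features()
    return {
        "n_rules": n_rules,
        "mean_literals_per_rule": (n_literals / n_rules) if n_rules else 0.0,
        "n_distinct_kmers": len(kmers),
    }


# --- JSON serialization ---------------------------------------------------


def _num(x: float):
    if x == INF:
        return "inf"
    if x == -INF:
        return "-inf"
    return x


def _unnum(x) -> float:
    if x == "inf":
        return INF
    if x == "-inf":
        return -INF
    return float(x)


def model_to_dict(model: RuleModel) -> dict:
    return {
        "rules": [
            {
                "literals": [
                    {
                        "kmer": lit.feature,
                        "intervals": [[_num(lo), _num(hi)] for lo, hi in lit.intervals],
                    }
                    for lit in rule.literals
                ],
                "class": rule.conclusion,
                "coverage": list(rule.coverage) if rule.coverage else None,
            }
            for rule in model.rules
        ],
        "default": model.default_class,
        "rank": model.rank,
        "learner": model.learner,
        "params": model.params,
        "seed": model.seed,
        "k": model.k,
    }


def model_from_dict(data: dict) -> RuleModel:
    rules = []
    for r in data["rules"]:
        literals = [
            Literal(
                feature=l["kmer"],
                intervals=tuple((_unnum(lo), _unnum(hi)) for lo, hi in l["intervals"]),
            )
            for l in r["literals"]
        ]
        coverage = tuple(r["coverage"]) if r.get("coverage") else None
        rules.append(Rule(literals=literals, conclusion=r["class"], coverage=coverage))
    return RuleModel(
        rules=rules,
        default_class=data["default"],
        rank=data.get("rank"),
        learner=data.get("learner", "manual"),
        params=data.get("params", {}),
        seed=data.get("seed"),
        k=data.get("k"),
    )


def save_model(model: RuleModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n")


def load_model(path: str | Path) -> RuleModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# --- human-readable text dialect ------------------------------------------

_COND_RANGE = re.compile(
    r"^\s*(?P<lo>[-+0-9.eE]+)\s*<=\s*f\((?P<kmer>[ACGT]+)\)\s*<\s*(?P<hi>[-+0-9.eE]+)\s*$"
)
_COND_ONE = re.compile(
    r"^\s*f\((?P<kmer>[ACGT]+)\)\s*(?P<op>>=|<=|<|>)\s*(?P<val>[-+0-9.eE]+)\s*$"
)


def _format_bound(x: float, scale: float) -> str:
    return f"{x * scale:.10g}"


def render_rule(rule: Rule, scale: float = 1e5) -> str:
    """Render one rule's condition with frequencies scaled for readability."""
    parts = []
    for lit in rule.literals:
        alts = []
        for lo, hi in lit.intervals:
            if lo == -INF and hi == INF:
                alts.append(f"f({lit.feature})>=-inf")
            elif lo == -INF:
                alts.append(f"f({lit.feature})<{_format_bound(hi, scale)}")
            elif hi == INF:
                alts.append(f"f({lit.feature})>={_format_bound(lo, scale)}")
            else:
                alts.append(
                    f"{_format_bound(lo, scale)}<=f({lit.feature})<{_format_bound(hi, scale)}"
                )
        parts.append(alts[0] if len(alts) == 1 else "(" + " | ".join(alts) + ")")
    return " & ".join(parts) if parts else "true"


def render_model(model: RuleModel, scale: float = 1e5) -> str:
    """Multi-line rendering: one ``class: condition`` line per rule plus default."""
    lines = [f"{rule.conclusion}: {render_rule(rule, scale)}" for rule in model.rules]
    lines.append(f"default: {model.default_class}")
    return "\n".join(lines) + "\n"


def _scaled(value_str: str, scale: float) -> float:
    # When the scale is an exact power of ten, fold it into the decimal
    # exponent so printed bounds round-trip to the exact double a user
    # writes as a literal (e.g. "42.82" at 1e-5 -> float("42.82e-5")).
    if scale > 0:
        exp = math.log10(scale)
        if exp == round(exp):
            return float(f"{value_str}e{int(round(exp))}")
    return float(value_str) * scale


def _parse_condition(text: str, scale: float) -> tuple[str, float, float]:
    m = _COND_RANGE.match(text)
    if m:
        return m["kmer"], _scaled(m["lo"], scale), _scaled(m["hi"], scale)
    m = _COND_ONE.match(text)
    if not m:
        raise ValidationError(f"cannot parse rule condition {text!r}")
    kmer, op, val = m["kmer"], m["op"], _scaled(m["val"], scale)
    if op in (">=",):
        return kmer, val, INF
    if op == ">":
        # frequencies are discrete multiples of 1/windows; strict > is kept
        # as a closed lower bound at the printed precision
        return kmer, math.nextafter(val, INF), INF
    if op == "<=":
        return kmer, -INF, math.nextafter(val, INF)
    return kmer, -INF, val


def _split_top(text: str, sep: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def parse_rule_line(line: str, scale: float = 1e-5) -> Rule:
    """Parse ``class: condition & condition ...`` into a :class:`Rule`.

    A parenthesized ``|``-group of conditions on a single feature becomes
    one union-interval literal. ``scale`` converts printed bounds back to
    the raw frequency scale (default assumes the 1e5 display scaling).
    """
    if ":" not in line:
        raise ValidationError(f"rule line lacks 'class:' prefix: {line!r}")
    conclusion, _, cond = line.partition(":")
    conclusion = conclusion.strip()
    literals: list[Literal] = []
    for part in _split_top(cond.strip(), "&"):
        part = part.strip()
        if not part or part == "true":
            continue
        if part.startswith("(") and part.endswith(")"):
            inner = part[1:-1]
            alts = [p.strip() for p in _split_top(inner, "|")]
            parsed = [_parse_condition(a, scale) for a in alts]
            kmers = {p[0] for p in parsed}
            if len(kmers) != 1:
                raise ValidationError(
                    f"disjunction must involve a single feature, got {sorted(kmers)}"
                )
            intervals = tuple(sorted((lo, hi) for _, lo, hi in parsed))
            literals.append(Literal(feature=parsed[0][0], intervals=intervals))
        else:
            kmer, lo, hi = _parse_condition(part, scale)
            literals.append(Literal.interval(kmer, lo, hi))
    if not literals:
        raise ValidationError(f"rule line has no conditions: {line!r}")
    return Rule(literals=literals, conclusion=conclusion)


def parse_rules(
    text: str, scale: float = 1e-5, default_class: str = "other"
) -> RuleModel:
    """Parse a rule-per-line text block into a :class:`RuleModel`.

    Lines starting with ``#`` and blank lines are ignored; a trailing
    ``default: <class>`` line sets the default class.
    """
    rules: list[Rule] = []
    default = default_class
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("default:"):
            default = line.partition(":")[2].strip()
            continue
        rules.append(parse_rule_line(line, scale))
    return RuleModel(rules=rules, default_class=default, learner="parsed")


def load_example_species_rules() -> RuleModel:
    """The bundled example species-level rule set for bacterial genomes.

    25 decision rules over 4-mer relative frequencies (display-scaled by
    1e5 in the file, stored raw in the model).
    """
    path = Path(__file__).parent / "data" / "example_species_rules.txt"
    return parse_rules(path.read_text())
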