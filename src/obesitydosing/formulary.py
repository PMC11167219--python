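"""Per-drug dosing-weight rules and opt-out weight selection.

A :class:`Formulary` maps drug names to :class:`DosingRule` records saying
which body weight (ideal, adjusted or actual) a per-kg dose should be
computed against, the maximum single dose, and the per-kg guideline range
used to judge flat (mg) doses. The packaged default covers the seven
high-risk IV medications of the dosing initiative; institutions supply
their own JSON document to extend or replace it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from .anthropometry import BodyWeights, ObesityAssessment, WeightKind
from .errors import DataIntegrityError, NotGovernedError, SchemaError


class RuleDoseUnit(str, Enum):
    """Unit a drug's guideline range is expressed in (per kg)."""

    MG = "mg"
    MCG_PER_KG_PER_HR = "mcg_per_kg_per_hr"


@dataclass(frozen=True)
class DosingRule:
    """Dosing-weight recommendation and guideline bounds for one drug."""

    drug: str
    recommended_weight_kind: WeightKind
    per_kg_low: float
    per_kg_high: float
    max_dose_mg: float | None = None
    dose_unit: RuleDoseUnit = RuleDoseUnit.MG
    route: str = "IV"
    level_monitored: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.per_kg_low > self.per_kg_high:
            raise SchemaError(
                f"rule {self.drug!r}: per_kg_low {self.per_kg_low} exceeds "
                f"per_kg_high {self.per_kg_high}"
            )
        if self.max_dose_mg is not None and self.max_dose_mg <= 0:
            raise SchemaError(f"rule {self.drug!r}: non-positive max dose")


def normalize_drug_name(name: str) -> str:
    """Canonical form used for all lookups: lowercase, trimmed."""
    return name.strip().lower()


class Formulary:
    """Case-insensitive mapping from drug name to :class:`DosingRule`."""

    def __init__(self, rules: Mapping[str, DosingRule] | list[DosingRule],
                 version_label: str = "unversioned"):
        self.version_label = version_label
        self._rules: dict[str, DosingRule] = {}
        items = rules.values() if isinstance(rules, Mapping) else rules
        for rule in items:
            key = normalize_drug_name(rule.drug)
            if key in self._rules:
                raise SchemaError(f"duplicate drug {key!r} in formulary")
            self._rules[key] = rule

    def __contains__(self, drug: str) -> bool:
        return normalize_drug_name(drug) in self._rules

    def __iter__(self) -> Iterator[DosingRule]:
        return iter(self._rules.values())

    def __len__(self) -> int:
        return len(self._rules)

    def lookup(self, drug: str) -> DosingRule:
        key = normalize_drug_name(drug)
        try:
            return self._rules[key]
        except KeyError:
            raise NotGovernedError(
                f"drug {drug!r} is not governed by formulary "
                f"{self.version_label!r}"
            ) from None

    def drugs(self) -> list[str]:
        return list(self._rules)

    def to_document(self) -> dict:
        """Serialize to the JSON document layout accepted by load_formulary."""
        return {
            "version": self.version_label,
            "rules": [
                {
                    "drug": r.drug,
                    "route": r.route,
                    "weight_kind": r.recommended_weight_kind.value,
                    "max_dose_mg": r.max_dose_mg,
                    "per_kg_low": r.per_kg_low,
                    "per_kg_high": r.per_kg_high,
                    "dose_unit": r.dose_unit.value,
                    "level_monitored": r.level_monitored,
                    "notes": r.notes,
                }
                for r in self
            ],
        }


@dataclass(frozen=True)
class WeightSelection:
    """The weight the order entry should use, with opt-out provenance.

    ``defaulted`` is True when the selection came from the opt-out default
    mechanism (the recommended alternative preselected for obese patients,
    actual weight otherwise); an ordering clinician overriding the default
    constructs a selection with ``defaulted=False``.
    """

    weight_kg: float
    weight_kind: WeightKind
    defaulted: bool = True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_REQUIRED_RULE_KEYS = {"drug", "weight_kind", "per_kg_low", "per_kg_high"}


def load_formulary(source: dict | str | Path) -> Formulary:
    """Build a Formulary from a JSON document (dict, JSON text, or path).

    The document has top-level ``version`` and a ``rules`` array; each rule
    carries ``drug``, ``weight_kind`` (ideal/adjusted/actual),
    ``max_dose_mg`` (nullable), ``per_kg_low``/``per_kg_high`` and
    ``dose_unit``. Structural problems raise :class:`SchemaError` naming
    the offending rule.
    """
    if isinstance(source, Path):
        doc = json.loads(source.read_text())
    elif isinstance(source, str):
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else source)
    else:
        doc = source
    if not isinstance(doc, dict) or "rules" not in doc:
        raise SchemaError("formulary document must be an object with a 'rules' array")
    rules: list[DosingRule] = []
    for raw in doc["rules"]:
        missing = _REQUIRED_RULE_KEYS - raw.keys()
        if missing:
            raise SchemaError(
                f"rule {raw.get('drug', '<unnamed>')!r}: missing keys {sorted(missing)}"
            )
        try:
            kind = WeightKind(raw["weight_kind"])
        except ValueError:
            raise SchemaError(
                f"rule {raw['drug']!r}: unknown weight kind {raw['weight_kind']!r}"
            ) from None
        try:
            unit = RuleDoseUnit(raw.get("dose_unit", "mg"))
        except ValueError:
            raise SchemaError(
                f"rule {raw['drug']!r}: unknown dose unit {raw['dose_unit']!r}"
            ) from None
        rules.append(
            DosingRule(
                drug=normalize_drug_name(raw["drug"]),
                recommended_weight_kind=kind,
                per_kg_low=float(raw["per_kg_low"]),
                per_kg_high=float(raw["per_kg_high"]),
                max_dose_mg=(
                    None if raw.get("max_dose_mg") is None else float(raw["max_dose_mg"])
                ),
                dose_unit=unit,
                route=raw.get("route", "IV"),
                level_monitored=bool(raw.get("level_monitored", False)),
                notes=raw.get("notes", ""),
            )
        )
    return Formulary(rules, version_label=str(doc.get("version", "unversioned")))


def default_formulary() -> Formulary:
    """The packaged seven-drug default formulary."""
    doc = json.loads(
        resources.files("obesitydosing.data")
        .joinpath("default_formulary.json")
        .read_text()
    )
    return load_formulary(doc)


def select_dosing_weight(
    assessment: ObesityAssessment,
    weights: BodyWeights,
    rule: DosingRule,
) -> WeightSelection:
    """Opt-out default dosing weight for one patient and drug.

    Obese patients default to the rule's recommended alternative weight;
    non-obese patients default to actual body weight. Overrides are
    expressed by the caller constructing a :class:`WeightSelection` with
    ``defaulted=False``.
    """
    if not assessment.obese:
        return WeightSelection(weights.actual_kg, WeightKind.ACTUAL, defaulted=True)
    kind = rule.recommended_weight_kind
    if kind is WeightKind.ADJUSTED and weights.adjusted_kg < weights.ideal_kg:
        raise DataIntegrityError(
            f"rule {rule.drug!r}: adjusted weight {weights.adjusted_kg} below "
            f"ideal {weights.ideal_kg}"
        )
    return WeightSelection(weights.weight_of_kind(kind), kind, defaulted=True)


def cap_dose(computed_dose: float, rule: DosingRule) -> float:
    """Apply the rule's maximum single dose to a computed mg dose.

    Identity for rate-based drugs or rules without a max.
    """
    if rule.max_dose_mg is None or rule.dose_unit is not RuleDoseUnit.MG:
        return computed_dose
    return min(computed_dose, rule.max_dose_mg)
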