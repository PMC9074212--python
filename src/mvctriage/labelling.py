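"""Retrospective labelling of the need for a lights-and-sirens response.

A crash is labelled as having needed an L&S ambulance response when any of
three clauses fires:

1. the ambulance priority from the scene to an emergency department was L&S;
2. anyone was dead on-scene or in transit;
3. anyone met at least one clinical L&S dispatch indicator.

The indicator set is a configurable rule table over interventions,
medications and observations.  The default set shipped with the package is
illustrative only (it mimics common prehospital red flags such as reduced
consciousness or hypotension) and carries no clinical authority; replace it
with a locally governed list before operational use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence


class LabellingError(ValueError):
    """A record cannot be labelled (missing clinical fields or profile)."""


@dataclass
class ClinicalProfile:
    """Per-incident clinical facts needed by the outcome rule.

    All three fields must be explicitly present: labelling never assumes a
    silent default for an absent clinical fact.
    """

    from_scene_priority_ls: Optional[bool] = None
    any_death: Optional[bool] = None
    indicator_flags: dict[str, bool] = field(default_factory=dict)


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


@dataclass(frozen=True)
class IndicatorRule:
    """One indicator: a named predicate ``field <op> threshold``."""

    name: str
    field: str
    operator: str
    threshold: float

    def fires(self, observations: Mapping[str, float]) -> bool:
        if self.field not in observations:
            raise LabellingError(f"indicator {self.name!r}: field {self.field!r} absent")
        value = observations[self.field]
        if value is None:
            raise LabellingError(f"indicator {self.name!r}: field {self.field!r} is null")
        return _OPS[self.operator](float(value), float(self.threshold))


@dataclass
class IndicatorRuleSet:
    """Named indicator predicates; an empty set is allowed, in which case the
    outcome reduces to the scene-priority and death clauses."""

    indicators: list[IndicatorRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.indicators]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")

    def evaluate(self, observations: Mapping[str, float]) -> dict[str, bool]:
        return {r.name: r.fires(observations) for r in self.indicators}

    @classmethod
    def from_json(cls, path: str | Path) -> "IndicatorRuleSet":
        entries = json.loads(Path(path).read_text())
        return cls([IndicatorRule(**e) for e in entries])

    @classmethod
    def default(cls) -> "IndicatorRuleSet":
        """Illustrative, non-authoritative indicator set."""
        return cls([
            IndicatorRule("reduced_consciousness", "gcs", "<", 13),
            IndicatorRule("hypotension", "systolic_bp", "<", 90),
            IndicatorRule("bradypnoea", "respiratory_rate", "<", 10),
            IndicatorRule("tachypnoea", "respiratory_rate", ">", 29),
            IndicatorRule("intubated", "intubation", "==", 1),
            IndicatorRule("adrenaline_given", "adrenaline", "==", 1),
        ])


def profile_from_observations(
    from_scene_priority_ls: bool,
    any_death: bool,
    observations: Mapping[str, float],
    rules: IndicatorRuleSet,
) -> ClinicalProfile:
    """Build a profile by evaluating the rule set on raw observations."""
    return ClinicalProfile(
        from_scene_priority_ls=bool(from_scene_priority_ls),
        any_death=bool(any_death),
        indicator_flags=rules.evaluate(observations),
    )


def label_record(profile: ClinicalProfile, rules: IndicatorRuleSet) -> int:
    """Apply the three-clause disjunction to one incident.

    ``rules`` defines which indicator names are consulted; an indicator
    named by the rule set but absent from the profile's flags is an error
    rather than an implicit False.
    """
    if profile.from_scene_priority_ls is None or profile.any_death is None:
        raise LabellingError("clinical profile incomplete: priority/death flag missing")
    if profile.from_scene_priority_ls or profile.any_death:
        return 1
    for rule in rules.indicators:
        if rule.name not in profile.indicator_flags:
            raise LabellingError(f"indicator flag {rule.name!r} missing from profile")
        if profile.indicator_flags[rule.name]:
            return 1
    return 0


def label_dataset(data, rules: IndicatorRuleSet):
    """Label every record of a dataset.

    Records carrying a precomputed label pass through unchanged; records
    with a clinical profile are labelled by :func:`label_record`; a record
    with neither is an error.
    """
    labels = []
    for i, rec in enumerate(data.records):
        if rec.label is not None:
            labels.append(int(rec.label))
        elif rec.clinical is not None:
            labels.append(label_record(rec.clinical, rules))
        else:
            raise LabellingError(f"record {i} has neither a label nor a clinical profile")
    return data.with_labels(labels)
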