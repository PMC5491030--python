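"""Declarative catalog of the behaviors under study.

The default catalog describes a two-wave lifestyle questionnaire: five focal
health behaviors (three of them health-*risk* behaviors whose frequencies are
reverse-scored so that every item points toward "healthier") and twenty-three
other lifestyle activities performed over the same two-week window.  Users can
define alternative behavior sets through JSON files with the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class Behavior:
    """One behavior item: a snake_case slug plus health/risk flags."""

    name: str
    is_health: bool = False
    is_risk: bool = False


@dataclass(frozen=True)
class BehaviorCatalog:
    """Ordered, validated collection of :class:`Behavior` records.

    Invariants: names unique; at least one health behavior; ``is_risk``
    implies ``is_health`` (only health items are reverse-scored).
    """

    behaviors: tuple[Behavior, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.behaviors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate behavior names: {dupes}")
        for b in self.behaviors:
            if b.is_risk and not b.is_health:
                raise ValueError(f"risk behavior {b.name!r} must be a health behavior")
        if not any(b.is_health for b in self.behaviors):
            raise ValueError("catalog needs at least one health behavior")
        if not any(not b.is_health for b in self.behaviors):
            raise ValueError("catalog needs at least one lifestyle behavior")

    # -- derived views -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviors)

    @property
    def health_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviors if b.is_health)

    @property
    def lifestyle_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviors if not b.is_health)

    @property
    def risk_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.behaviors if b.is_risk)

    def __len__(self) -> int:
        return len(self.behaviors)

    # -- JSON interface ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            [
                {"name": b.name, "is_health": b.is_health, "is_risk": b.is_risk}
                for b in self.behaviors
            ],
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n", encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "BehaviorCatalog":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        records = json.loads(text)
        return cls(
            tuple(
                Behavior(r["name"], bool(r.get("is_health", False)), bool(r.get("is_risk", False)))
                for r in records
            )
        )

    @classmethod
    def from_behaviors(cls, behaviors: Iterable[Behavior]) -> "BehaviorCatalog":
        return cls(tuple(behaviors))


#: Five health behaviors; smoking, getting drunk and fast food are risk items.
_HEALTH = [
    Behavior("exercise", is_health=True),
    Behavior("smoking", is_health=True, is_risk=True),
    Behavior("getting_drunk", is_health=True, is_risk=True),
    Behavior("eat_fruit", is_health=True),
    Behavior("eat_fast_food", is_health=True, is_risk=True),
]

#: Twenty-three other lifestyle activities sharing the two-week window.
_LIFESTYLE = [
    "buy_magazine",
    "buy_newspaper",
    "read_for_pleasure",
    "take_vitamins",
    "visit_friend",
    "eat_out",
    "attend_lectures",
    "sleep_seven_hours",
    "buy_clothes",
    "no_lie_in",
    "go_to_cinema",
    "go_for_walk",
    "independent_study",
    "write_letter",
    "recycle_bottles",
    "visit_countryside",
    "go_to_library",
    "avoid_meat",
    "rent_video",
    "go_shopping",
    "visit_parents",
    "go_clubbing",
    "tidy_room",
]


def default_catalog() -> BehaviorCatalog:
    """The 28-behavior default catalog (5 health + 23 lifestyle)."""
    return BehaviorCatalog(tuple(_HEALTH) + tuple(Behavior(n) for n in _LIFESTYLE))
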