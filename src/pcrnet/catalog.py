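"""The 40-item symptom instrument and its named subsets.

The instrument covers a major depressive episode (10 items), DSM-IV PTSD minus
traumatic amnesia (16 items), four anxiety-disorder screens, dissociation, and
single-item screens for commonly co-occurring problems (self-harm, substance
abuse, pain, impairment, ...).  Item ids are 1-based and stable; abbreviations
are the short codes used in network figures.  Three subsets are predefined:
ANX (items 1-4), REEXP (the five PTSD criterion-B reexperiencing items, 5-9)
and DEP (the ten depression items).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

CATEGORIES = frozenset(
    {"ANX", "PTSD", "MDD", "DISSOC", "OTHER", "IMPAIRMENT", "PTSD&MDD"}
)

N_ITEMS = 40


@dataclass(frozen=True)
class SymptomItem:
    """One instrument item: integer id (1-40), label, short code, category."""

    id: int
    label: str
    abbreviation: str
    category: str

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_ITEMS:
            raise ValueError(f"item id must be in 1..{N_ITEMS}, got {self.id}")
        if not self.label or not self.abbreviation:
            raise ValueError(f"item {self.id}: empty label or abbreviation")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"item {self.id}: unknown category {self.category!r}"
            )


_DEFAULT_ITEMS: tuple[tuple[int, str, str, str], ...] = (
    (1, "Panic attacks", "PANC", "ANX"),
    (2, "Anxious worrying", "WRRY", "ANX"),
    (3, "Social anxiety", "SCAX", "ANX"),
    (4, "Agoraphobic behavior", "AGOR", "ANX"),
    (5, "Intrusive memories of a traumatic event", "MEMT", "PTSD"),
    (6, "Dreams/nightmares about a traumatic event", "DRM", "PTSD"),
    (7, "Emotional upset at reminder of a traumatic event", "EMOT", "PTSD"),
    (8, "Physiological reaction at reminder of a traumatic event", "PHYS", "PTSD"),
    (9, "Flashbacks of a traumatic event", "FLSH", "PTSD"),
    (10, "Avoidance of thoughts/feelings about a traumatic event", "AVTH", "PTSD"),
    (11, "Avoidance of reminders of a traumatic event", "AVAC", "PTSD"),
    (12, "Loss of interest", "LSIN", "PTSD&MDD"),
    (13, "Depressed mood", "DPRM", "MDD"),
    (14, "Feeling distant or cut off from others", "DIST", "PTSD"),
    (15, "Emotional numbness", "NUMB", "PTSD"),
    (16, "Sense of foreshortened future / loss of core life goals", "FRZN", "PTSD"),
    (17, "Irritability/anger", "IRRI", "PTSD"),
    (18, "Thinking/concentration problems", "DCNC", "PTSD&MDD"),
    (19, "Hypervigilance", "HVGL", "PTSD"),
    (20, "Strong startle reactions", "STRT", "PTSD"),
    (21, "Derealization", "DREA", "DISSOC"),
    (22, "Depersonalization", "DPRS", "DISSOC"),
    (23, "Identity confusion", "IDCF", "DISSOC"),
    (24, "Feeling worthless", "WRTL", "MDD"),
    (25, "Guilt and/or shame", "SHME", "OTHER"),
    (26, "Self-harming behavior", "SHRM", "OTHER"),
    (27, "Suicidal thinking/behavior", "SUIC", "MDD"),
    (28, "Psychomotor agitation", "AGIT", "MDD"),
    (29, "Psychomotor slowing", "SLOW", "MDD"),
    (30, "Energy loss/fatigue", "FTIG", "MDD"),
    (31, "Hypomania", "HPOM", "OTHER"),
    (32, "Sleeping problems", "SLP", "PTSD&MDD"),
    (33, "Eating problems", "EAT", "MDD"),
    (34, "Sexual problems", "SEX", "OTHER"),
    (35, "Pain problems", "PAIN", "OTHER"),
    (36, "Interpersonal problems", "SCRL", "IMPAIRMENT"),
    (37, "Work and/or school problems", "WRK", "IMPAIRMENT"),
    (38, "Alcohol/substance abuse problems", "ALC", "OTHER"),
    (39, "Lost time", "TIME", "DISSOC"),
    (40, "Hearing voices inside your head", "VOIC", "DISSOC"),
)

_DEFAULT_SUBSETS: Mapping[str, tuple[int, ...]] = {
    "ANX": (1, 2, 3, 4),
    "REEXP": (5, 6, 7, 8, 9),
    "DEP": (12, 13, 18, 24, 27, 28, 29, 30, 32, 33),
}

#: item id of the single guilt-and/or-shame screen used in the moderated
#: mediation design
SHAME_ITEM = 25


@dataclass(frozen=True)
class SymptomCatalog:
    """The full instrument: an ordered item list plus named index subsets."""

    items: tuple[SymptomItem, ...]
    subsets: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"catalog must have {N_ITEMS} items, got {len(self.items)}")
        ids = [it.id for it in self.items]
        if sorted(ids) != list(range(1, N_ITEMS + 1)):
            raise ValueError("item ids must be exactly 1..40 and unique")
        abbrs = {it.abbreviation for it in self.items}
        if len(abbrs) != N_ITEMS:
            raise ValueError("item abbreviations must be unique")
        valid = set(ids)
        for name, members in self.subsets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"subset {name!r} has repeated item ids")
            if not set(members) <= valid:
                raise ValueError(f"subset {name!r} references unknown item ids")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(it.id for it in self.items)

    def item(self, item_id: int) -> SymptomItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(f"unknown symptom id {item_id}")

    def subset_ids(self, name: str) -> tuple[int, ...]:
        try:
            return tuple(self.subsets[name])
        except KeyError:
            raise KeyError(f"unknown subset {name!r}") from None

    def resolve(self, scope: str | Iterable[int] | None) -> tuple[int, ...]:
        """Resolve a scope (None = all items, a subset name, or explicit ids)."""
        if scope is None:
            return self.ids
        if isinstance(scope, str):
            return self.subset_ids(scope)
        return tuple(int(i) for i in scope)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "id": it.id,
                    "label": it.label,
                    "abbreviation": it.abbreviation,
                    "category": it.category,
                }
                for it in self.items
            ],
            "subsets": {k: list(v) for k, v in self.subsets.items()},
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SymptomCatalog":
        items = tuple(
            SymptomItem(
                id=int(d["id"]),
                label=str(d["label"]),
                abbreviation=str(d["abbreviation"]),
                category=str(d["category"]),
            )
            for d in payload["items"]
        )
        subsets = {k: tuple(int(i) for i in v) for k, v in payload.get("subsets", {}).items()}
        return cls(items=items, subsets=subsets)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SymptomCatalog":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_catalog() -> SymptomCatalog:
    """The standard 40-item instrument with the ANX / REEXP / DEP subsets."""
    return SymptomCatalog(
        items=tuple(SymptomItem(*row) for row in _DEFAULT_ITEMS),
        subsets=dict(_DEFAULT_SUBSETS),
    )
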