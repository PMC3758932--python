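"""Participant-level data with typed missingness.

A participant contributes a 0-7 frequency rating per item ("How frequently have
you experienced this problem in the past month?") and, for every ordered pair
of items both endorsed at least once in the past month, a 0-10 perceived-causal
-relation (PCR) rating of how much the first symptom causes the second.

Missingness is typed.  A PCR slot whose endpoints were not both endorsed was
never asked: missing *by design*.  A question that was presented but skipped is
missing *by intention*.  By-design slots are implicit — they are derivable from
the frequencies, are never stored or serialized, and are surfaced through
:meth:`ParticipantRecord.pcr_status`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .catalog import SymptomCatalog

FREQ_MIN, FREQ_MAX = 0, 7
PCR_MIN, PCR_MAX = 0, 10


class Missing(enum.Enum):
    """Typed missing codes for ratings."""

    BY_DESIGN = "by_design"
    BY_INTENTION = "by_intention"


#: a frequency cell: ordinal 0-7 when present, else missing by intention
FrequencyRating = int | Missing

#: a PCR cell as stored: ordinal 0-10 when present, else missing by intention
PCRRating = int | Missing


class PCRDataError(ValueError):
    """Malformed or internally inconsistent PCR-scaling data."""


def _check_frequency(value: int) -> int:
    if not FREQ_MIN <= value <= FREQ_MAX:
        raise PCRDataError(f"frequency must be in {FREQ_MIN}..{FREQ_MAX}, got {value}")
    return int(value)


def _check_pcr(value: int) -> int:
    if not PCR_MIN <= value <= PCR_MAX:
        raise PCRDataError(f"PCR rating must be in {PCR_MIN}..{PCR_MAX}, got {value}")
    return int(value)


@dataclass
class ParticipantRecord:
    """One respondent: per-item frequencies plus the sparse directed PCR map.

    ``frequencies`` maps every catalog item id to an ordinal 0-7 or
    ``Missing.BY_INTENTION`` (skipped, or absent from the input file).
    ``pcr`` holds exactly the *eligible* ordered pairs — both endpoints with
    frequency >= 1 — mapped to an ordinal 0-10 or ``Missing.BY_INTENTION``.
    """

    participant_id: str
    frequencies: dict[int, FrequencyRating] = field(default_factory=dict)
    pcr: dict[tuple[int, int], PCRRating] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------

    def frequency(self, item_id: int) -> FrequencyRating:
        return self.frequencies[item_id]

    def endorsed(self) -> tuple[int, ...]:
        """Item ids rated at least 'Once in the past month' (frequency >= 1)."""
        return tuple(
            i for i in sorted(self.frequencies)
            if isinstance(self.frequencies[i], int) and self.frequencies[i] >= 1
        )

    def eligible_pairs(self) -> list[tuple[int, int]]:
        """All ordered pairs (i, j), i != j, with both endpoints endorsed.

        Lexicographic (i, j) order; these are exactly the PCR questions the
        adaptive procedure asks, so the count is k*(k-1) for k endorsed items.
        """
        endorsed = self.endorsed()
        return [(i, j) for i in endorsed for j in endorsed if i != j]

    def pcr_status(self, cause_id: int, effect_id: int) -> PCRRating:
        """Value, BY_INTENTION, or BY_DESIGN for any ordered item pair."""
        if cause_id == effect_id:
            raise PCRDataError("a symptom cannot be paired with itself")
        try:
            return self.pcr[(cause_id, effect_id)]
        except KeyError:
            return Missing.BY_DESIGN

    def pcr_present(self) -> dict[tuple[int, int], int]:
        """The present (answered) PCR ratings only."""
        return {k: v for k, v in self.pcr.items() if isinstance(v, int)}

    def n_pcr_present(self) -> int:
        return sum(1 for v in self.pcr.values() if isinstance(v, int))

    # -- validation ------------------------------------------------------

    def validate(self, catalog: SymptomCatalog) -> "ParticipantRecord":
        """Check every record invariant against the catalog; return self."""
        valid_ids = set(catalog.ids)
        if set(self.frequencies) != valid_ids:
            raise PCRDataError(
                f"participant {self.participant_id}: frequencies must cover "
                f"all {len(valid_ids)} catalog items"
            )
        for i, v in self.frequencies.items():
            if isinstance(v, int):
                _check_frequency(v)
            elif v is not Missing.BY_INTENTION:
                raise PCRDataError(
                    f"participant {self.participant_id}, item {i}: frequency "
                    f"may be an int or missing by intention, got {v!r}"
                )
        eligible = set(self.eligible_pairs())
        stored = set(self.pcr)
        if stored - eligible:
            bad = sorted(stored - eligible)[0]
            raise PCRDataError(
                f"participant {self.participant_id}: PCR entry for ineligible "
                f"pair {bad} (an endpoint has frequency 0 or missing)"
            )
        if eligible - stored:
            bad = sorted(eligible - stored)[0]
            raise PCRDataError(
                f"participant {self.participant_id}: eligible pair {bad} has "
                f"no PCR entry"
            )
        for k, v in self.pcr.items():
            if isinstance(v, int):
                _check_pcr(v)
            elif v is not Missing.BY_INTENTION:
                raise PCRDataError(
                    f"participant {self.participant_id}, pair {k}: stored PCR "
                    f"may be an int or missing by intention, got {v!r}"
                )
        return self


def subset_frequency_score(
    record: ParticipantRecord,
    subset: str,
    catalog: SymptomCatalog,
    mode: str = "mean",
) -> float | None:
    """Aggregate frequency over a named subset (available-case).

    Items rated 0 contribute 0; by-intention items are dropped.  Returns None
    when every subset item is missing.  ``mode`` is "mean" (default, robust to
    skipped items) or "sum".
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    ids = catalog.subset_ids(subset)
    values = [record.frequencies[i] for i in ids if isinstance(record.frequencies[i], int)]
    if not values:
        return None
    return float(sum(values)) / (len(values) if mode == "mean" else 1)


def frequency_sum_score(
    record: ParticipantRecord, items: Iterable[int] | None = None
) -> float:
    """Symptom-burden score: sum of available frequency ratings.

    Defaults to all 40 items (the total used in the feedback-loop analysis);
    pass ``items`` to restrict, e.g. to non-impairment items.
    """
    ids = items if items is not None else record.frequencies.keys()
    return float(
        sum(
            record.frequencies[i]
            for i in ids
            if isinstance(record.frequencies[i], int)
        )
    )


def validate_records(
    records: Iterable[ParticipantRecord], catalog: SymptomCatalog
) -> list[ParticipantRecord]:
    return [r.validate(catalog) for r in records]
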