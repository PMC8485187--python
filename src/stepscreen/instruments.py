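"""Item-level scoring of the PHQ-9, GAD-7 and AUDIT screeners.

All three instruments are scored as simple item sums.  The PHQ-9 and
GAD-7 totals are additionally mapped to severity bands
(:mod:`stepscreen.bands`); the AUDIT total is carried through unbanded
for the GP's consideration.  Incomplete questionnaires are rejected
outright — there is no proration rule, because silently imputing items
would move patients across band boundaries invisibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .bands import (
    GAD7_CUTOFFS,
    PHQ9_CUTOFFS,
    BandCutoffs,
    SeverityBand,
    SuicidalityLevel,
)
from .errors import InstrumentValidationError

__all__ = [
    "Instrument",
    "ItemResponses",
    "InstrumentScore",
    "score_phq9",
    "score_gad7",
    "score_audit",
    "grade_suicidality",
]


class Instrument(str, Enum):
    PHQ9 = "PHQ9"
    GAD7 = "GAD7"
    AUDIT = "AUDIT"


# Legal response sets per item.  PHQ-9/GAD-7 items are 0-3 Likert.
# AUDIT items 1-8 are scored 0-4; items 9 and 10 only take 0, 2 or 4.
_PHQ9_ITEM_SETS: tuple[frozenset[int], ...] = (frozenset(range(4)),) * 9
_GAD7_ITEM_SETS: tuple[frozenset[int], ...] = (frozenset(range(4)),) * 7
_AUDIT_ITEM_SETS: tuple[frozenset[int], ...] = (frozenset(range(5)),) * 8 + (
    frozenset({0, 2, 4}),
    frozenset({0, 2, 4}),
)

_ITEM_SETS = {
    Instrument.PHQ9: _PHQ9_ITEM_SETS,
    Instrument.GAD7: _GAD7_ITEM_SETS,
    Instrument.AUDIT: _AUDIT_ITEM_SETS,
}


@dataclass(frozen=True)
class ItemResponses:
    """A complete, validated item-response vector for one instrument."""

    instrument: Instrument
    items: tuple[int, ...]

    def __post_init__(self):
        item_sets = _ITEM_SETS[Instrument(self.instrument)]
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        items = tuple(self.items)
        if len(items) != len(item_sets):
            raise InstrumentValidationError(
                f"{self.instrument.value} requires {len(item_sets)} items, got {len(items)}"
            )
        for i, (value, legal) in enumerate(zip(items, item_sets)):
            if not isinstance(value, (int,)) or isinstance(value, bool):
                try:
                    if value != int(value):
                        raise ValueError
                    value = int(value)
                except (TypeError, ValueError):
                    raise InstrumentValidationError(
                        f"{self.instrument.value} item {i + 1} is not an integer: {value!r}",
                        index=i,
                    ) from None
            if value not in legal:
                raise InstrumentValidationError(
                    f"{self.instrument.value} item {i + 1} = {value} outside legal "
                    f"values {sorted(legal)}",
                    index=i,
                )
        object.__setattr__(self, "items", tuple(int(v) for v in items))

    @property
    def total(self) -> int:
        return sum(self.items)


@dataclass(frozen=True)
class InstrumentScore:
    """Instrument total with its severity band (``None`` for the AUDIT)."""

    instrument: Instrument
    total: int
    band: SeverityBand | None


def _score_banded(items: ItemResponses, expect: Instrument, cutoffs: BandCutoffs) -> InstrumentScore:
    if items.instrument != expect:
        raise InstrumentValidationError(
            f"expected {expect.value} responses, got {items.instrument.value}"
        )
    total = items.total
    return InstrumentScore(expect, total, cutoffs.band(total))


def score_phq9(items: ItemResponses, cutoffs: BandCutoffs = PHQ9_CUTOFFS) -> InstrumentScore:
    """Score the 9-item depression screener: total 0-27 plus severity band."""
    return _score_banded(items, Instrument.PHQ9, cutoffs)


def score_gad7(items: ItemResponses, cutoffs: BandCutoffs = GAD7_CUTOFFS) -> InstrumentScore:
    """Score the 7-item anxiety screener: total 0-21 plus severity band."""
    return _score_banded(items, Instrument.GAD7, cutoffs)


def score_audit(items: ItemResponses) -> InstrumentScore:
    """Score the 10-item alcohol-use screener.

    Only the total (0-40) is computed; risk-zone interpretation is left to
    the GP, so no band is attached.
    """
    if items.instrument != Instrument.AUDIT:
        raise InstrumentValidationError(
            f"expected AUDIT responses, got {items.instrument.value}"
        )
    return InstrumentScore(Instrument.AUDIT, items.total, None)


def grade_suicidality(item9: int) -> SuicidalityLevel:
    """Grade suicidal ideation from the raw PHQ-9 item-9 response.

    The mapping is the identity: 0 none, 1 mild, 2 moderate, 3 severe.
    """
    if isinstance(item9, bool) or item9 not in (0, 1, 2, 3):
        raise InstrumentValidationError(
            f"PHQ-9 item 9 must be 0-3, got {item9!r}", index=8
        )
    return SuicidalityLevel(item9)


def phq9_responses(items: Sequence[int]) -> ItemResponses:
    """Convenience constructor for PHQ-9 item vectors."""
    return ItemResponses(Instrument.PHQ9, tuple(items))


def gad7_responses(items: Sequence[int]) -> ItemResponses:
    return ItemResponses(Instrument.GAD7, tuple(items))


def audit_responses(items: Sequence[int]) -> ItemResponses:
    return ItemResponses(Instrument.AUDIT, tuple(items))
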