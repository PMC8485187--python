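"""Severity bands and suicidality grades.

The engine stratifies symptom severity into four ordinal bands per
instrument.  Defaults follow the deployed screening tool's cutoffs:

* PHQ-9 (total 0-27): nil-minimal 0-4, mild 5-9, moderate 10-19,
  severe 20-27.  Note the moderate band deliberately spans 10-19,
  merging the conventional moderate and moderately-severe PHQ-9 bands.
* GAD-7 (total 0-21): nil-minimal 0-4, mild 5-9, moderate 10-14,
  severe 15-21.

Suicidal ideation is graded directly from PHQ-9 item 9 (0 none,
1 mild, 2 moderate, 3 severe) and reported alongside — never inside —
the severity stratification.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = [
    "SeverityBand",
    "SuicidalityLevel",
    "BandCutoffs",
    "PHQ9_CUTOFFS",
    "GAD7_CUTOFFS",
    "band_for_total",
]


class SeverityBand(IntEnum):
    """Ordinal symptom-severity category; comparisons use the ordinal order."""

    NIL_MINIMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class SuicidalityLevel(IntEnum):
    """Graded suicidal-ideation level, equal to the raw PHQ-9 item-9 response."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


class BandCutoffs:
    """Inclusive upper bounds of the four severity bands, in band order.

    ``uppers[i]`` is the largest total still inside band ``i``; the last
    entry is the instrument maximum.  Immutable: sensitivity analyses build
    a new instance rather than mutating the defaults.
    """

    __slots__ = ("uppers",)

    def __init__(self, uppers: tuple[int, int, int, int]):
        if len(uppers) != 4 or list(uppers) != sorted(uppers):
            raise ValueError(f"cutoffs must be 4 non-decreasing upper bounds, got {uppers!r}")
        object.__setattr__(self, "uppers", tuple(int(u) for u in uppers))

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("BandCutoffs is immutable")

    def __repr__(self):
        return f"BandCutoffs({self.uppers!r})"

    def __eq__(self, other):
        return isinstance(other, BandCutoffs) and self.uppers == other.uppers

    def __hash__(self):
        return hash(self.uppers)

    @property
    def max_total(self) -> int:
        return self.uppers[-1]

    def band(self, total: int) -> SeverityBand:
        if not 0 <= total <= self.max_total:
            raise ValueError(f"total {total} outside [0, {self.max_total}]")
        for level, upper in enumerate(self.uppers):
            if total <= upper:
                return SeverityBand(level)
        raise AssertionError("unreachable")  # pragma: no cover

    def band_range(self, band: SeverityBand) -> tuple[int, int]:
        """Inclusive (lo, hi) total range of ``band``."""
        lo = 0 if band == 0 else self.uppers[band - 1] + 1
        return lo, self.uppers[band]


PHQ9_CUTOFFS = BandCutoffs((4, 9, 19, 27))
GAD7_CUTOFFS = BandCutoffs((4, 9, 14, 21))


def band_for_total(total: int, cutoffs: BandCutoffs) -> SeverityBand:
    """Map an instrument total onto its severity band."""
    return cutoffs.band(total)
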