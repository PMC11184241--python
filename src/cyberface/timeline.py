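"""Analysis timeline: segments and 15-second intervals.

After discarding the lead-in (the experimenter typing names and picking the
condition), the game is analyzed on a 1-based clock of "analysis seconds".
The session is split into three temporal segments capturing the course of
the inclusion/ostracism manipulation, and into ten intervals of roughly
15 seconds each used for the aggregated pattern tables.

The third interval spans 14 seconds (31-44) and the last one 10 seconds
(136-145); the remaining eight span 15 or 16 seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Seconds discarded at the start of each recording before analysis.
DEFAULT_LEAD_S = 14.0

_SEGMENTS = {1: (1, 59), 2: (60, 105), 3: (106, 145)}
_INTERVALS = {
    1: (1, 15),
    2: (16, 30),
    3: (31, 44),
    4: (45, 59),
    5: (60, 75),
    6: (76, 90),
    7: (91, 105),
    8: (106, 120),
    9: (121, 135),
    10: (136, 145),
}


@dataclass(frozen=True)
class Timeline:
    """Segment and interval boundaries in closed 1-based analysis seconds."""

    segments: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(_SEGMENTS)
    )
    intervals: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(_INTERVALS)
    )

    def __post_init__(self) -> None:
        covered: list[int] = []
        for lo, hi in self.intervals.values():
            if lo > hi:
                raise ValueError(f"empty interval ({lo}, {hi})")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(min(covered), max(covered) + 1)):
            raise ValueError("intervals must be disjoint and contiguous")
        if len(covered) != len(set(covered)):
            raise ValueError("intervals overlap")

    @property
    def n_seconds(self) -> int:
        return max(hi for _, hi in self.intervals.values())

    def interval_seconds(self, interval: int) -> range:
        lo, hi = self.intervals[interval]
        return range(lo, hi + 1)

    def segment_seconds(self, segment: int) -> range:
        lo, hi = self.segments[segment]
        return range(lo, hi + 1)

    def segment_of(self, second: int) -> int:
        for seg, (lo, hi) in self.segments.items():
            if lo <= second <= hi:
                return seg
        raise ValueError(f"second {second} outside all segments")


DEFAULT_TIMELINE = Timeline()
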