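"""Canonical emotion labels and experimental conditions.

Automated facial coding scores seven primary emotions on a continuous
[0, 1] intensity scale, plus a neutral channel.  The tuple order below is
the canonical column order used everywhere in this package; it also serves
as the deterministic tie-break order when two emotions share the same
per-second score.
"""

from __future__ import annotations

EMOTIONS: tuple[str, ...] = (
    "happiness",
    "sadness",
    "anger",
    "surprise",
    "fear",
    "disgust",
    "contempt",
)

NEUTRAL = "neutral"

#: Cyberball conditions: the subject either keeps receiving the ball
#: (inclusion) or is ostracized after an initial warm-up (exclusion).
CONDITIONS: tuple[str, str] = ("inclusion", "exclusion")

N_EMOTIONS = len(EMOTIONS)


def validate_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(
            f"condition must be one of {CONDITIONS}, got {condition!r}"
        )
    return condition
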