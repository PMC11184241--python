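"""Trapezium AUC per emotion, segment AUCs, masked emotions, proportions.

The area under each emotion's per-second intensity curve summarizes how
much of that emotion a subject expressed over a span of the game.  Because
subjects were recorded at different native frame rates (30 or 60 fps),
AUCs computed on the per-second series are rescaled to a common 30-frame
per-second abscissa, making them comparable across subjects.

"Masking" — covering a negative emotion with a smile — is operationalized
additively: each non-happiness emotion's AUC is summed with the happiness
AUC of the same subject, condition and scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emotions import EMOTIONS
from .timeline import DEFAULT_TIMELINE, Timeline

#: Common frame axis all AUCs are standardized to, in frames per second.
REF_FPS = 30

SCOPES = ("total", "segment1", "segment2", "segment3")


def trapezium_auc(series, dx: float = 1.0) -> float:
    """Trapezium-rule integral of an intensity series with step ``dx``."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("trapezium_auc needs a 1-d series of length >= 2")
    return float(np.trapezoid(y, dx=dx))


def standardize_auc(raw_auc: float, fps: int, ref_fps: int = REF_FPS) -> float:
    """Rescale a per-second-axis AUC onto a common frame-count axis.

    The per-second series already absorbed the native frame rate (each
    second is the mean of its 30 or 60 frames), so placing everyone on the
    reference axis is a single multiplication by ``ref_fps`` — identical
    intensity profiles recorded at 30 and 60 fps standardize identically.
    """
    if fps not in (30, 60):
        raise ValueError(f"fps must be 30 or 60, got {fps}")
    return raw_auc * ref_fps


def segment_aucs(
    series: pd.DataFrame,
    timeline: Timeline = DEFAULT_TIMELINE,
    fps: int = REF_FPS,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-emotion AUC for each segment and for the whole series.

    ``series`` is a per-second DataFrame (seconds x 7 emotions).  Segments
    with fewer than two observed seconds yield NaN.  Returns a long table
    with columns scope, emotion, auc.
    """
    scale = REF_FPS if standardize else 1.0
    rows = []
    scopes: dict[str, pd.Index] = {
        "total": series.index,
        **{
            f"segment{s}": series.index.intersection(
                list(timeline.segment_seconds(s))
            )
            for s in timeline.segments
        },
    }
    for scope, secs in scopes.items():
        sub = series.loc[secs]
        for e in EMOTIONS:
            auc = (
                trapezium_auc(sub[e].to_numpy(), dx=1.0) * scale
                if len(sub) >= 2
                else np.nan
            )
            rows.append({"scope": scope, "emotion": e, "auc": auc})
    return pd.DataFrame(rows)


def masked_auc(records: pd.DataFrame) -> pd.DataFrame:
    """Sum each non-happiness emotion's AUC with the happiness AUC.

    ``records`` is a long AUC table with an ``emotion`` and ``auc`` column
    and any grouping columns (e.g. subject, condition, scope).  A missing
    happiness row within a group is an error.
    """
    group_cols = [c for c in records.columns if c not in ("emotion", "auc")]
    out = []
    grouped = records.groupby(group_cols, sort=False) if group_cols else [((), records)]
    for key, sub in grouped:
        happy = sub.loc[sub["emotion"] == "happiness", "auc"]
        if happy.empty:
            raise ValueError(f"no happiness AUC for group {key}")
        h = float(happy.iloc[0])
        masked = sub[sub["emotion"] != "happiness"].copy()
        masked["masked_auc"] = masked["auc"] + h
        out.append(masked)
    return pd.concat(out, ignore_index=True)


def proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Share of each emotion in the summed AUC of its group (pie-chart data).

    Adds a ``share`` column; groups whose seven AUCs sum to zero get NaN
    shares and ``degenerate=True``.
    """
    group_cols = [c for c in records.columns if c not in ("emotion", "auc")]
    out = records.copy()
    if group_cols:
        totals = out.groupby(group_cols)["auc"].transform("sum")
    else:
        totals = pd.Series(out["auc"].sum(), index=out.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["share"] = np.where(totals > 0, out["auc"] / totals, np.nan)
    out["degenerate"] = ~(totals > 0)
    return out
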