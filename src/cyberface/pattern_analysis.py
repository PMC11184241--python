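"""Dominant-emotion pattern analysis.

Because an expression must persist for about half a second to count as an
emotional state, the frame stream is first collapsed to per-second mean
intensities.  The group-level "pattern" is then, for every analysis second,
the percentage of subjects whose dominant (highest-scoring) emotion that
second is each of the seven categories.  Patterns are aggregated over the
ten roughly-15-second intervals of the timeline, contrasted between the
exclusion and inclusion conditions, and screened with a comparative-error
criterion for the difference of two proportions at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emotions import EMOTIONS
from .io_facereader import EmptyRecordingError, Recording
from .timeline import DEFAULT_TIMELINE, Timeline


def per_second_means(rec: Recording) -> pd.DataFrame:
    """Collapse a (trimmed) recording to per-second mean intensities.

    Analysis second ``s`` (1-based) averages the frames with
    ``time_s in [s-1, s)``; a trailing partial second is dropped.  Returns a
    DataFrame indexed by second with one column per canonical emotion.
    """
    if rec.n_frames == 0:
        raise EmptyRecordingError("cannot average an empty recording")
    t = rec.frames["time_s"].to_numpy(float)
    second = np.floor(t + 1e-9).astype(int) + 1
    df = rec.intensity_matrix().copy()
    df.index = second
    out = df.groupby(level=0).mean()
    counts = df.groupby(level=0).size()
    last = out.index[-1]
    if counts.loc[last] < rec.fps:
        out = out.drop(index=last)
    if out.empty:
        raise EmptyRecordingError("recording shorter than one full second")
    out.index.name = "second"
    return out


def dominant_per_second(series: pd.DataFrame) -> pd.Series:
    """Label each second with its dominant emotion.

    Ties are broken by the canonical emotion order; the neutral channel
    never competes.  The returned Series carries ``attrs['n_tied']`` and
    ``attrs['n_all_zero']`` diagnostics.
    """
    cols = [c for c in EMOTIONS if c in series.columns]
    if len(cols) != len(EMOTIONS):
        raise ValueError("series must contain all seven emotions")
    vals = series[list(EMOTIONS)].to_numpy(float)
    idx = vals.argmax(axis=1)  # argmax takes the first max: canonical order
    labels = pd.Series(
        np.asarray(EMOTIONS, dtype=object)[idx], index=series.index, name="dominant"
    )
    is_max = vals == vals.max(axis=1, keepdims=True)
    labels.attrs["n_tied"] = int((is_max.sum(axis=1) > 1).sum())
    labels.attrs["n_all_zero"] = int((vals.max(axis=1) == 0).sum())
    return labels


@dataclass
class GroupPattern:
    """Per-second percentage of subjects showing each dominant emotion.

    ``percentages`` is seconds x 7 (rows sum to 100 wherever at least one
    subject is on-record; seconds with no subject are NaN), ``n_subjects``
    the per-second denominator.
    """

    percentages: pd.DataFrame
    n_subjects: pd.Series

    def __len__(self) -> int:
        return len(self.percentages)

    @property
    def complete_prefix(self) -> "GroupPattern":
        """Restrict to the leading run of seconds where every subject is on-record."""
        full = self.n_subjects == self.n_subjects.max()
        if not full.iloc[0]:
            raise ValueError("no complete seconds at the start of the pattern")
        stop = full.idxmin() if not full.all() else full.index[-1] + 1
        return GroupPattern(
            self.percentages.loc[: stop - 1], self.n_subjects.loc[: stop - 1]
        )


def group_percentages(
    dominants: dict[str, pd.Series],
    timeline: Timeline = DEFAULT_TIMELINE,
) -> GroupPattern:
    """Pool per-subject dominant labels into a group pattern.

    Subjects whose recording ended before a given second are excluded from
    that second's denominator; a second covered by nobody is NaN.
    """
    if not dominants:
        raise ValueError("need at least one subject")
    seconds = pd.RangeIndex(1, timeline.n_seconds + 1, name="second")
    all_secs = np.concatenate(
        [s.index.to_numpy() for s in dominants.values()]
    )
    all_labels = np.concatenate([s.to_numpy() for s in dominants.values()])
    keep = (all_secs >= 1) & (all_secs <= timeline.n_seconds)
    counts = (
        pd.crosstab(all_secs[keep], all_labels[keep])
        .reindex(index=seconds, columns=list(EMOTIONS))
        .fillna(0.0)
    )
    n = counts.sum(axis=1).astype(int).rename("n_subjects")
    n.index.name = "second"
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts.div(n.replace(0, np.nan), axis=0)
    pct = pct.dropna(how="all")
    pct.index.name = "second"
    return GroupPattern(pct, n.loc[pct.index])


def interval_means(
    pattern: GroupPattern, timeline: Timeline = DEFAULT_TIMELINE
) -> pd.DataFrame:
    """Average a pattern over the timeline's intervals.

    Returns a 7 x 10 grid (emotions x intervals); each fully-observed
    column sums to 100.  Intervals with no observed seconds are NaN.
    """
    grid = pd.DataFrame(
        np.nan, index=list(EMOTIONS), columns=list(timeline.intervals)
    )
    grid.columns.name = "interval"
    for i in timeline.intervals:
        secs = pattern.percentages.index.intersection(
            list(timeline.interval_seconds(i))
        )
        if len(secs):
            grid[i] = pattern.percentages.loc[secs].mean(axis=0)
    return grid


def condition_difference(
    excl: pd.DataFrame, incl: pd.DataFrame
) -> pd.DataFrame:
    """Exclusion-minus-inclusion difference of two interval grids."""
    if excl.shape != incl.shape or list(excl.index) != list(incl.index):
        raise ValueError("interval grids have mismatched shape or labels")
    return excl - incl


def extremes_per_interval(grid: pd.DataFrame) -> pd.DataFrame:
    """Most and least common emotion per interval (canonical tie-break)."""
    rows = []
    for i in grid.columns:
        col = grid[i].to_numpy(float)
        if np.isnan(col).all():
            rows.append({"interval": i, "most": None, "least": None})
            continue
        rows.append(
            {
                "interval": i,
                "most": EMOTIONS[int(np.nanargmax(col))],
                "least": EMOTIONS[int(np.nanargmin(col))],
            }
        )
    return pd.DataFrame(rows).set_index("interval")


@dataclass(frozen=True)
class ComparativeError:
    """Comparative-error screen for the difference of two proportions.

    ``ce`` is the half-width, in percentage points, of the 95% (for
    ``z = 1.96``) confidence band for the difference of two independent
    proportions; a difference exceeding it is deemed significant.  With the
    study's 14 subjects per condition even a 24-point swing fails this bar,
    which is the sample-size caveat the screen exists to make explicit.
    """

    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    ce: float
    diff: float

    @property
    def significant(self) -> bool:
        return self.diff > self.ce


def comparative_error(
    p1: float, p2: float, n1: int, n2: int, z: float = 1.96
) -> ComparativeError:
    """Compare two percentages from groups of size n1 and n2."""
    for p in (p1, p2):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"percentage {p} outside [0, 100]")
    if min(n1, n2) < 1:
        raise ValueError("group sizes must be >= 1")
    q1, q2 = p1 / 100.0, p2 / 100.0
    ce = 100.0 * z * math.sqrt(q1 * (1 - q1) / n1 + q2 * (1 - q2) / n2)
    return ComparativeError(p1, p2, n1, n2, z, ce, abs(p2 - p1))


def pattern_to_long(pattern: GroupPattern, condition: str) -> pd.DataFrame:
    """Long-format (second, emotion, percentage, condition) table for export."""
    long = (
        pattern.percentages.reset_index()
        .melt(id_vars="second", var_name="emotion", value_name="percentage")
        .sort_values(["second", "emotion"], kind="stable")
        .reset_index(drop=True)
    )
    long["condition"] = condition
    return long
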