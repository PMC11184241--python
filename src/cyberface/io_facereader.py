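"""Reading, writing and calibrating FaceReader-style frame logs.

A detailed export holds one row per video frame: a timestamp and continuous
[0, 1] intensity scores for the seven primary emotions, optionally plus a
neutral channel.  This module parses those logs into :class:`Recording`
objects, trims the discarded lead-in, and implements the software's
continuous-calibration rule, which corrects each frame's raw intensity
against the running average of the frames seen so far so that scores adapt
to a person's idiosyncratic resting face:

    calibrated(l_a) = max(0, (l_a - l_m) / (1 - l_a))

where ``l_a`` is the raw intensity in the current frame and ``l_m`` the mean
raw intensity over all *previous* frames.  The neutral channel is corrected
with the running maximum of those per-emotion means, ``l_max_m``:

    calibrated_neutral(N_a) = (N_a + (1 - l_max_m)) / 2

Calibration is off by default throughout the pipeline: vendor exports are
already calibrated, and these operations exist to emulate the documented
behaviour on raw streams.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .emotions import EMOTIONS, NEUTRAL, validate_condition

logger = logging.getLogger(__name__)

VALID_FPS = (30, 60)

#: Plausible total-recording duration window in seconds (game sessions run
#: a bit over two minutes; the window is deliberately generous).
DEFAULT_DURATION_WINDOW = (105.0, 160.0)


class FormatError(ValueError):
    """The file does not look like a frame log (missing columns, bad dialect)."""


class ValidationError(ValueError):
    """The file parsed but violates an invariant (e.g. intensity out of [0,1])."""


class EmptyRecordingError(ValueError):
    """An operation would leave no frames."""


@dataclass
class Recording:
    """One subject x condition frame-level intensity stream.

    ``frames`` holds one row per frame with a ``time_s`` column (seconds from
    recording start, strictly increasing, spaced ~1/fps) and one column per
    canonical emotion plus ``neutral``.
    """

    subject_id: str
    condition: str
    fps: int
    frames: pd.DataFrame
    duration_window: tuple[float, float] | None = DEFAULT_DURATION_WINDOW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_condition(self.condition)
        if self.fps not in VALID_FPS:
            raise ValidationError(f"fps must be in {VALID_FPS}, got {self.fps}")
        cols = ["time_s", *EMOTIONS, NEUTRAL]
        missing = [c for c in cols if c not in self.frames.columns]
        if missing:
            raise FormatError(f"frames missing columns: {missing}")
        self.frames = self.frames.loc[:, cols].reset_index(drop=True)
        t = self.frames["time_s"].to_numpy(float)
        if len(t) == 0:
            raise EmptyRecordingError("recording has no frames")
        if t[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(
                    f"timestamps not strictly increasing at frame {bad}"
                )
            step = 1.0 / self.fps
            if not np.allclose(dt, step, atol=0.25 * step):
                raise ValidationError(
                    f"timestamps not spaced ~1/{self.fps} s"
                )
        vals = self.frames[[*EMOTIONS, NEUTRAL]].to_numpy(float)
        if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
            rows = np.where(
                ~np.isfinite(vals).all(axis=1)
                | (vals < 0).any(axis=1)
                | (vals > 1).any(axis=1)
            )[0]
            raise ValidationError(
                f"intensities outside [0, 1] at frame row(s) {rows[:5].tolist()}"
            )
        if self.duration_window is not None and not self.meta.get("trimmed"):
            lo, hi = self.duration_window
            if not (lo - 1e-6 <= self.duration_s <= hi + 1e-6):
                raise ValidationError(
                    f"duration {self.duration_s:.1f} s outside window [{lo}, {hi}]"
                )

    @property
    def duration_s(self) -> float:
        t = self.frames["time_s"].to_numpy(float)
        return float(t[-1] - t[0] + 1.0 / self.fps)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def intensity_matrix(self) -> pd.DataFrame:
        """Frames x 7 emotion intensities (neutral excluded)."""
        return self.frames[list(EMOTIONS)]


_TIME_ALIASES = ("time_s", "time", "timestamp", "video time", "video_time", "t")
_HMS_RE = re.compile(r"^(\d+):(\d{1,2}):(\d{1,2}(?:\.\d+)?)$")


def _parse_time(value) -> float:
    """Accept plain seconds or an ``HH:MM:SS.fff`` clock string."""
    if isinstance(value, str):
        m = _HMS_RE.match(value.strip())
        if m:
            h, mnt, s = m.groups()
            return int(h) * 3600 + int(mnt) * 60 + float(s)
    return float(value)


def read_recording(
    path: str | Path,
    subject_id: str,
    condition: str,
    fps: int,
    **kwargs,
) -> Recording:
    """Read a delimited frame log (CSV/TSV autodetected) into a Recording.

    The header must name a timestamp column and the seven emotions (any
    capitalization); a neutral column is optional and defaults to zero.
    Unknown extra columns are ignored with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower().strip(): c for c in df.columns}

    time_col = next((lower[a] for a in _TIME_ALIASES if a in lower), None)
    if time_col is None:
        raise FormatError(f"{path}: no timestamp column among {_TIME_ALIASES}")
    missing = [e for e in EMOTIONS if e not in lower]
    if missing:
        raise FormatError(f"{path}: missing emotion column(s) {missing}")

    known = {time_col, *(lower[e] for e in EMOTIONS)}
    if NEUTRAL in lower:
        known.add(lower[NEUTRAL])
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)

    out = pd.DataFrame({"time_s": df[time_col].map(_parse_time)})
    for e in EMOTIONS:
        out[e] = pd.to_numeric(df[lower[e]], errors="coerce")
    out[NEUTRAL] = (
        pd.to_numeric(df[lower[NEUTRAL]], errors="coerce")
        if NEUTRAL in lower
        else 0.0
    )

    vals = out[[*EMOTIONS, NEUTRAL]].to_numpy(float)
    bad = np.where(
        ~np.isfinite(vals).all(axis=1)
        | (vals < 0).any(axis=1)
        | (vals > 1).any(axis=1)
    )[0]
    if len(bad):
        raise ValidationError(
            f"{path}: intensity outside [0, 1] (or non-numeric) in data row "
            f"{int(bad[0]) + 1}"
        )
    return Recording(subject_id, condition, int(fps), out, **kwargs)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording back to CSV in the same dialect read_recording accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.frames.to_csv(path, index=False, float_format="%.6f")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest: columns subject_id, condition, fps, path."""
    df = pd.read_csv(path)
    required = {"subject_id", "condition", "fps", "path"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    return df


def load_cohort(manifest_path: str | Path, **kwargs) -> list[Recording]:
    """Load every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recs = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        recs.append(
            read_recording(
                p, str(row.subject_id), row.condition, int(row.fps), **kwargs
            )
        )
    return recs


def trim_lead(rec: Recording, lead_s: float = 14.0) -> Recording:
    """Drop the first ``lead_s`` seconds and re-zero the timestamps.

    The start of each video is occupied by the experimenter entering the
    participant's name and choosing the condition; those frames carry no
    game-related expression and are discarded before any analysis.
    """
    if lead_s == 0:
        return rec
    if rec.duration_s <= lead_s:
        raise EmptyRecordingError(
            f"recording lasts {rec.duration_s:.1f} s <= lead of {lead_s} s"
        )
    frames = rec.frames[rec.frames["time_s"] >= lead_s].copy()
    frames["time_s"] = frames["time_s"] - frames["time_s"].iloc[0]
    return replace(rec, frames=frames, meta={**rec.meta, "trimmed": True})


def calibrate_intensity(l_a: float, l_m: float) -> float:
    """Continuous-calibration rule for one emotion intensity.

    Returns ``max(0, (l_a - l_m) / (1 - l_a))``; zero whenever the current
    frame does not exceed the running mean.
    """
    if not (0.0 <= l_a < 1.0):
        if l_a == 1.0:
            raise ZeroDivisionError("l_a = 1 makes the calibration singular")
        raise ValidationError(f"l_a must be in [0, 1), got {l_a}")
    if not (0.0 <= l_m <= 1.0):
        raise ValidationError(f"l_m must be in [0, 1], got {l_m}")
    return max(0.0, (l_a - l_m) / (1.0 - l_a))


def calibrate_neutral(n_a: float, l_max_m: float) -> float:
    """Calibrated neutral intensity, ``(N_a + (1 - l_max_m)) / 2`` in [0, 1]."""
    if not (0.0 <= n_a <= 1.0) or not (0.0 <= l_max_m <= 1.0):
        raise ValidationError("calibrate_neutral inputs must be in [0, 1]")
    return (n_a + (1.0 - l_max_m)) / 2.0


def apply_continuous_calibration(rec: Recording) -> Recording:
    """Apply the running-mean calibration to every frame of a recording.

    Frame ``i`` uses per-emotion means over frames ``1..i-1`` (the first
    frame uses 0: no prior evidence, raw intensity passes through) and the
    running maximum of those means for the neutral channel.  Raw intensities
    of exactly 1 are nudged to ``1 - 1e-9``; calibrated values above 1 are
    clamped back into [0, 1] with a logged count.
    """
    raw = rec.intensity_matrix().to_numpy(float)
    n = len(raw)
    # prefix means: row i holds the mean of rows 0..i-1; row 0 is all zero
    prefix = np.zeros_like(raw)
    if n > 1:
        prefix[1:] = np.cumsum(raw[:-1], axis=0) / np.arange(1, n)[:, None]
    l_max_m = np.maximum.accumulate(prefix.max(axis=1))

    la = np.where(raw >= 1.0, 1.0 - 1e-9, raw)
    cal = np.maximum(0.0, (la - prefix) / (1.0 - la))
    clipped = int((cal > 1.0).sum())
    if clipped:
        logger.info(
            "%s/%s: clamped %d calibrated intensities above 1",
            rec.subject_id,
            rec.condition,
            clipped,
        )
    cal = np.clip(cal, 0.0, 1.0)

    neutral = (rec.frames[NEUTRAL].to_numpy(float) + (1.0 - l_max_m)) / 2.0
    frames = rec.frames.copy()
    frames[list(EMOTIONS)] = cal
    frames[NEUTRAL] = np.clip(neutral, 0.0, 1.0)
    return replace(rec, frames=frames, meta={**rec.meta, "calibrated": True})
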