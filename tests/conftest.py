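import numpy as np
import pandas as pd
import pytest

from cyberface import EMOTIONS, NEUTRAL, Recording


def make_recording(
    intensities: dict[str, list[float]] | None = None,
    n_frames: int = 90,
    fps: int = 30,
    subject_id: str = "S01",
    condition: str = "inclusion",
    fill: float = 0.0,
) -> Recording:
    """Small in-memory recording; unspecified emotions are constant ``fill``."""
    frames = pd.DataFrame({"time_s": np.arange(n_frames) / fps})
    for e in EMOTIONS:
        vals = (intensities or {}).get(e, fill)
        frames[e] = np.resize(np.asarray(vals, dtype=float), n_frames) if np.ndim(vals) else vals
    frames[NEUTRAL] = 0.0
    return Recording(subject_id, condition, fps, frames, duration_window=None)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions (seeded)."""
    from cyberface import default_paper_spec, generate_cohort

    return generate_cohort(default_paper_spec(seed=1234))


@pytest.fixture(scope="session")
def cohort_series(default_cohort):
    """Per-second series per (subject, condition) for the default cohort."""
    from cyberface import per_second_means, trim_lead

    return {
        (r.subject_id, r.condition): per_second_means(trim_lead(r))
        for r in default_cohort.recordings
    }
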