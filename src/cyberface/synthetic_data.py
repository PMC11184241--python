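"""Synthetic cohorts of emotion streams and clinical scores.

No public recordings exist for this paradigm, so every downstream stage is
exercised on simulated cohorts that carry the statistical structure the
analysis assumes:

* frame-level intensity streams per subject x condition, built from a
  latent Gaussian AR(1) process per emotion (baseline + subject offset +
  condition/segment effects) mapped through a logistic link into [0, 1] —
  intensities are not constrained to sum to one, matching automated facial
  coding output;
* a default effect structure emulating the reported phenomenology:
  sadness the most frequent dominant emotion throughout, an anger
  condition x segment interaction (rising late in inclusion, fading late
  in exclusion), and a late-exclusion rise of happiness and surprise;
* clinical scales drawn from a Gaussian copula whose Spearman correlations
  hit the published inter-scale targets, with truncated-normal marginals
  calibrated to the published means/SDs, and a Need Threat Scale shift
  between conditions (means 78.50 vs 110.57, SD 29).

Everything is a pure function of the spec's integer seed (PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, signal, stats

from .emotions import CONDITIONS, EMOTIONS, NEUTRAL
from .io_facereader import Recording, write_recording
from .timeline import DEFAULT_LEAD_S, DEFAULT_TIMELINE


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# --- spec -------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """A latent-scale shift for one emotion in one condition.

    ``segments`` lists the timeline segments the effect covers (treated as
    one contiguous span); ``shape`` is ``constant`` (flat shift of
    ``magnitude``) or ``linear-ramp`` (0 up to ``magnitude`` across the
    span).
    """

    emotion: str
    condition: str
    segments: tuple[int, ...]
    shape: str = "linear-ramp"
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not set(self.segments) <= {1, 2, 3}:
            raise ValueError("segments must be within {1, 2, 3}")
        if self.shape not in ("constant", "linear-ramp"):
            raise ValueError("shape must be 'constant' or 'linear-ramp'")


#: Latent (logit-scale) baselines; logistic(baseline) is the typical resting
#: intensity (~0.02-0.05, the magnitude automated coding reports for most
#: emotions most of the time).  The spacing was calibrated once, against the
#: published early-game inclusion dominant-emotion shares (before any
#: injected condition effects act), so that under the default latent
#: dispersion the argmax probabilities reproduce the observed prominence
#: ranking: sadness on top (~30%), contempt (~23%) and anger (~19%) next,
#: fear and disgust rare but not absent (~2-3%).
DEFAULT_BASELINE: dict[str, float] = {
    "happiness": -3.14,
    "sadness": -2.90,
    "anger": -3.05,
    "surprise": -3.22,
    "fear": -3.51,
    "disgust": -3.63,
    "contempt": -2.98,
}

#: Published inter-scale Spearman correlations used as copula targets.
DEFAULT_SCALE_CORRELATIONS = pd.DataFrame(
    [
        [1.00, 0.37, 0.65, 0.68, 0.14],
        [0.37, 1.00, 0.16, 0.23, -0.02],
        [0.65, 0.16, 1.00, 0.32, -0.08],
        [0.68, 0.23, 0.32, 1.00, 0.12],
        [0.14, -0.02, -0.08, 0.12, 1.00],
    ],
    index=["scid_ii", "bis15", "best", "ders_e", "nts"],
    columns=["scid_ii", "bis15", "best", "ders_e", "nts"],
)

#: Marginal (mean, sd, low, high) per scale, from the published cohort
#: description; subscale entries carry their parent total.
SCALE_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "scid_ii": (12.36, 2.0, 0.0, 15.0),
    "bis15": (49.79, 13.0, 15.0, 75.0),
    "bis15_cognitive": (15.93, 5.0, 5.0, 25.0),
    "bis15_motor": (13.79, 4.0, 5.0, 25.0),
    "bis15_nonplanning": (19.93, 5.0, 5.0, 25.0),
    "best": (44.00, 11.0, 12.0, 72.0),
    "best_a": (30.00, 6.0, 8.0, 40.0),
    "best_b": (13.43, 4.0, 4.0, 20.0),
    "best_c": (12.07, 3.0, 3.0, 15.0),
    "ders_e": (81.08, 15.0, 24.0, 120.0),
    "nts_inclusion": (78.50, 29.0, 14.0, 140.0),
    "nts_exclusion": (110.57, 29.0, 14.0, 140.0),
}

_SUBSCALES: dict[str, tuple[str, ...]] = {
    "bis15": ("bis15_cognitive", "bis15_motor", "bis15_nonplanning"),
    "best": ("best_a", "best_b", "best_c"),
}


def _default_effects() -> tuple[EffectSpec, ...]:
    """Condition effects emulating the reported phenomenology.

    Magnitudes were fitted once so that the segment-average dominant-emotion
    shares they imply match the published late-game profiles: anger rising
    to ~27% of subjects late in inclusion while fading to ~9% late in
    exclusion (the condition x segment interaction), and happiness (~28%)
    and surprise (~18%) climbing late in exclusion.
    """
    return (
        EffectSpec("anger", "inclusion", (3,), "linear-ramp", 0.31),
        EffectSpec("anger", "exclusion", (3,), "linear-ramp", -0.31),
        EffectSpec("happiness", "exclusion", (3,), "linear-ramp", 0.57),
        EffectSpec("surprise", "exclusion", (2, 3), "linear-ramp", 0.31),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Everything that determines a synthetic cohort.

    ``duration_s`` is the *total* recording duration window in seconds,
    lead-in included; ``noise_sd`` is the stationary SD of the per-second
    latent AR(1) fluctuation; ``subject_sd`` the SD of the per-subject,
    per-emotion latent offset shared across conditions (this is what makes
    a subject's AUCs correlate between inclusion and exclusion).
    """

    n_subjects: int = 14
    fps_assignment: dict[str, int] | None = None
    duration_s: tuple[float, float] = (139.0, 160.0)
    lead_s: float = DEFAULT_LEAD_S
    baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    effects: tuple[EffectSpec, ...] = field(default_factory=_default_effects)
    ar_coefficient: float = 0.7
    noise_sd: float = 0.4
    subject_sd: float = 0.15
    frame_noise_sd: float = 0.3
    nts_means: tuple[float, float] = (78.50, 110.57)
    nts_sd: float = 29.0
    nts_cross_condition_rho: float = 0.6
    scale_correlations: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_SCALE_CORRELATIONS.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        c = self.scale_correlations
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("scale_correlations must be symmetric with unit diagonal")

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def fps_of(self) -> dict[str, int]:
        """Frame-rate per subject: by default all at 30 fps except the last
        two at 60 fps, mirroring the recorded cohort (12 at 30, 2 at 60)."""
        if self.fps_assignment is not None:
            return dict(self.fps_assignment)
        ids = self.subject_ids()
        fps = {s: 30 for s in ids}
        if self.n_subjects > 2:
            for s in ids[-2:]:
                fps[s] = 60
        return fps

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "n_subjects": self.n_subjects,
            "fps_assignment": self.fps_assignment,
            "duration_s": list(self.duration_s),
            "lead_s": self.lead_s,
            "baseline": self.baseline,
            "effects": [
                {
                    "emotion": e.emotion,
                    "condition": e.condition,
                    "segments": list(e.segments),
                    "shape": e.shape,
                    "magnitude": e.magnitude,
                }
                for e in self.effects
            ],
            "ar_coefficient": self.ar_coefficient,
            "noise_sd": self.noise_sd,
            "subject_sd": self.subject_sd,
            "frame_noise_sd": self.frame_noise_sd,
            "nts_means": list(self.nts_means),
            "nts_sd": self.nts_sd,
            "nts_cross_condition_rho": self.nts_cross_condition_rho,
            "seed": self.seed,
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        data = yaml.safe_load(Path(path).read_text())
        if "effects" in data:
            data["effects"] = tuple(
                EffectSpec(
                    e["emotion"], e["condition"], tuple(e["segments"]),
                    e.get("shape", "linear-ramp"), e.get("magnitude", 1.0),
                )
                for e in data["effects"]
            )
        if "duration_s" in data:
            data["duration_s"] = tuple(data["duration_s"])
        if "nts_means" in data:
            data["nts_means"] = tuple(data["nts_means"])
        return cls(**data)


def default_paper_spec(seed: int = 0) -> CohortSpec:
    """The spec whose defaults emulate the published study conditions."""
    return CohortSpec(seed=seed)


def interaction_probe_spec(delta: float = 1.0, seed: int = 0) -> CohortSpec:
    """A cohort spec with *only* the anger condition x segment interaction.

    Anger shifts by ``+delta`` late in inclusion and ``-delta`` late in
    exclusion (latent scale, segment 3), with no other injected effects —
    the canonical positive control for the repeated-measures interaction
    test.  The default ``delta`` is large against the latent noise SD.
    """
    return CohortSpec(
        effects=(
            EffectSpec("anger", "inclusion", (3,), "linear-ramp", delta),
            EffectSpec("anger", "exclusion", (3,), "linear-ramp", -delta),
        ),
        seed=seed,
    )


# --- recordings -------------------------------------------------------------

def _effect_track(
    spec: CohortSpec, emotion: str, condition: str, n_analysis_s: int
) -> np.ndarray:
    """Per-analysis-second latent shift from all matching effect specs."""
    track = np.zeros(n_analysis_s)
    for eff in spec.effects:
        if eff.emotion != emotion or eff.condition != condition:
            continue
        lo = min(DEFAULT_TIMELINE.segments[s][0] for s in eff.segments)
        hi = max(DEFAULT_TIMELINE.segments[s][1] for s in eff.segments)
        lo_i, hi_i = lo - 1, min(hi, n_analysis_s) - 1
        if lo_i > hi_i:
            continue
        span = hi - lo
        if eff.shape == "constant" or span == 0:
            track[lo_i : hi_i + 1] += eff.magnitude
        else:
            ramp = eff.magnitude * (np.arange(lo - 1, hi) - (lo - 1)) / span
            track[lo_i : hi_i + 1] += ramp[: hi_i - lo_i + 1]
    return track


def _simulate_recording(
    spec: CohortSpec,
    subject_id: str,
    condition: str,
    fps: int,
    u_subject: np.ndarray,
    rng: np.random.Generator,
) -> Recording:
    total_s = int(round(rng.uniform(*spec.duration_s)))
    lead = int(spec.lead_s)
    n_analysis_s = total_s - lead
    if n_analysis_s < 2:
        raise ValueError("duration window leaves no analyzed material")

    phi = spec.ar_coefficient
    innov_sd = spec.noise_sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=(total_s, len(EMOTIONS)))
    eps[0] = rng.normal(0.0, spec.noise_sd, size=len(EMOTIONS))
    ar = signal.lfilter([1.0], [1.0, -phi], eps, axis=0)

    latent = ar + np.array([spec.baseline[e] for e in EMOTIONS]) + u_subject
    for j, e in enumerate(EMOTIONS):
        latent[lead:, j] += _effect_track(spec, e, condition, n_analysis_s)

    per_frame = np.repeat(latent, fps, axis=0)
    per_frame = per_frame + rng.normal(
        0.0, spec.frame_noise_sd, size=per_frame.shape
    )
    intens = _logistic(per_frame)

    frames = pd.DataFrame(intens, columns=list(EMOTIONS))
    frames.insert(0, "time_s", np.arange(len(frames)) / fps)
    frames[NEUTRAL] = np.clip(1.0 - intens.max(axis=1), 0.0, 1.0)
    return Recording(
        subject_id,
        condition,
        fps,
        frames,
        duration_window=None,
        meta={"synthetic": True, "total_s": total_s},
    )


# --- clinical scores --------------------------------------------------------

def _spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Gaussian-copula latent correlation matching a Spearman target."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def _truncnorm_ppf(u, mean, sd, low, high):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


@lru_cache(maxsize=None)
def _calibrated_loc(target_mean: float, sd: float, low: float, high: float) -> float:
    """Underlying normal location whose truncated mean equals the target."""

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo, hi = low - 10 * sd, high + 10 * sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi))


def _marginal(u: np.ndarray, name: str, target_mean: float | None = None) -> np.ndarray:
    mean, sd, low, high = SCALE_MARGINALS[name]
    if target_mean is not None:
        mean = target_mean
    loc = _calibrated_loc(mean, sd, low, high)
    return _truncnorm_ppf(u, loc, sd, low, high)


def generate_scores(
    spec: CohortSpec,
    n_subjects: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw clinical scores for ``n_subjects`` via the Gaussian copula.

    The copula couples SCID-II, BIS-15, BEST, DERS-E and a latent NTS trait
    at the target Spearman correlations (converted to latent Pearson via
    ``2 sin(pi rho / 6)``); the NTS trait splits into per-condition scores
    correlated ``nts_cross_condition_rho`` across conditions with the
    condition-specific means.  Subscales are generated conditionally on
    their parent total (latent loading 0.8).  All marginals are truncated
    normals whose post-truncation mean is calibrated to the published mean.
    """
    n = spec.n_subjects if n_subjects is None else n_subjects
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed).spawn(2)[0]
        )
    rho_s = spec.scale_correlations.loc[
        ["scid_ii", "bis15", "best", "ders_e", "nts"],
        ["scid_ii", "bis15", "best", "ders_e", "nts"],
    ].to_numpy(float)
    pearson = _spearman_to_pearson(rho_s)
    np.fill_diagonal(pearson, 1.0)
    # split the nts row into one latent per condition
    k = pearson.shape[0]
    full = np.zeros((k + 1, k + 1))
    full[:k, :k] = pearson
    full[k, :k] = full[:k, k] = pearson[4, :k]
    full[4, k] = full[k, 4] = 2.0 * np.sin(
        np.pi * spec.nts_cross_condition_rho / 6.0
    )
    np.fill_diagonal(full, 1.0)
    eig = np.linalg.eigvalsh(full)
    if eig.min() < -1e-10:
        raise ValueError(
            "scale correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eig.min():.3g})"
        )
    z = rng.multivariate_normal(
        np.zeros(k + 1), full, size=n, method="cholesky"
    )
    u = stats.norm.cdf(z)
    scores = pd.DataFrame({"subject_id": [f"S{i + 1:02d}" for i in range(n)]})
    scores["scid_ii"] = _marginal(u[:, 0], "scid_ii")
    scores["bis15"] = _marginal(u[:, 1], "bis15")
    scores["best"] = _marginal(u[:, 2], "best")
    scores["ders_e"] = _marginal(u[:, 3], "ders_e")
    scores["nts_inclusion"] = _truncnorm_ppf(
        stats.norm.cdf(z[:, 4]),
        _calibrated_loc(spec.nts_means[0], spec.nts_sd, 14.0, 140.0),
        spec.nts_sd, 14.0, 140.0,
    )
    scores["nts_exclusion"] = _truncnorm_ppf(
        stats.norm.cdf(z[:, 5]),
        _calibrated_loc(spec.nts_means[1], spec.nts_sd, 14.0, 140.0),
        spec.nts_sd, 14.0, 140.0,
    )
    lam = 0.8
    parent_z = {"bis15": z[:, 1], "best": z[:, 2]}
    for parent, subs in _SUBSCALES.items():
        for s in subs:
            zs = lam * parent_z[parent] + np.sqrt(1 - lam**2) * rng.normal(size=n)
            scores[s] = _marginal(stats.norm.cdf(zs), s)
    return scores


# --- cohort -----------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Recordings (one per subject per condition) plus clinical scores."""

    recordings: list[Recording]
    scores: pd.DataFrame
    spec: CohortSpec

    def recording(self, subject_id: str, condition: str) -> Recording:
        for r in self.recordings:
            if r.subject_id == subject_id and r.condition == condition:
                return r
        raise KeyError((subject_id, condition))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministic in ``spec.seed``."""
    ss = np.random.SeedSequence(spec.seed)
    ss_scores, ss_rec = ss.spawn(2)
    scores = generate_scores(spec, rng=np.random.default_rng(ss_scores))
    fps = spec.fps_of()
    recordings = []
    rec_streams = ss_rec.spawn(spec.n_subjects)
    for sid, stream in zip(spec.subject_ids(), rec_streams):
        rng = np.random.default_rng(stream)
        u_subject = rng.normal(0.0, spec.subject_sd, size=len(EMOTIONS))
        for condition in CONDITIONS:
            recordings.append(
                _simulate_recording(spec, sid, condition, fps[sid], u_subject, rng)
            )
    return SyntheticCohort(recordings, scores, spec)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write per-recording CSVs, a manifest, scores and the spec to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        name = f"{rec.subject_id}_{rec.condition}.csv"
        write_recording(rec, outdir / name)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                "fps": rec.fps,
                "path": name,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.scores.to_csv(outdir / "scores.csv", index=False)
    cohort.spec.to_yaml(outdir / "cohort_spec.yaml")
    return manifest
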