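"""End-to-end orchestration: cohort -> patterns -> null -> AUC -> inference.

``run_pipeline`` either simulates a cohort or ingests one from a manifest,
then runs every analysis stage and writes plain CSV/JSON outputs with a
config hash in each table header, so an output tree is a pure, diffable
function of (inputs, config, master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emotions import CONDITIONS, EMOTIONS
from .io_facereader import load_cohort, trim_lead
from .timeline import DEFAULT_LEAD_S, DEFAULT_TIMELINE, Timeline
from . import pattern_analysis as pat
from . import auc_masking as auc
from . import shuffle_null as shuf
from . import stats_inference as inf
from .synthetic_data import CohortSpec, default_paper_spec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: ``simulate`` (a :class:`CohortSpec`, defaulting
    to the study-conditions spec) or ``manifest`` (path to a cohort
    manifest CSV, with an optional scores CSV alongside).  The master seed
    fans out to named child streams (simulation, shuffling) so stages can
    be re-run in isolation reproducibly.
    """

    mode: str = "simulate"
    cohort_spec: CohortSpec | None = None
    manifest_path: str | None = None
    scores_path: str | None = None
    output_dir: str = "cyberface_out"
    seed: int = 0
    lead_s: float = DEFAULT_LEAD_S
    calibrate: bool = False
    shuffle_k: int = 1
    z_critical: float = 1.96
    transforms: dict[str, str] = field(
        default_factory=lambda: dict(inf.DEFAULT_TRANSFORMS)
    )
    correction: str = "benjamini-hochberg"
    timeline: Timeline = field(default_factory=lambda: DEFAULT_TIMELINE)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "manifest"):
            raise ValueError("mode must be 'simulate' or 'manifest'")
        if self.mode == "manifest" and not self.manifest_path:
            raise ValueError("manifest mode needs manifest_path")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "mode": self.mode,
                "manifest": self.manifest_path,
                "seed": self.seed,
                "lead_s": self.lead_s,
                "calibrate": self.calibrate,
                "shuffle_k": self.shuffle_k,
                "z": self.z_critical,
                "transforms": self.transforms,
                "correction": self.correction,
                "spec_seed": None if self.cohort_spec is None else self.cohort_spec.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _child_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output tree; returns a run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    tl = config.timeline

    # --- inputs -------------------------------------------------------
    if config.mode == "simulate":
        spec = config.cohort_spec or default_paper_spec(
            seed=_child_seed(config.seed, "simulate")
        )
        cohort = generate_cohort(spec)
        recordings, scores = cohort.recordings, cohort.scores
    else:
        recordings = load_cohort(config.manifest_path)
        scores = pd.read_csv(config.scores_path) if config.scores_path else None

    if config.calibrate:
        from .io_facereader import apply_continuous_calibration

        recordings = [apply_continuous_calibration(r) for r in recordings]

    # --- per-subject series ------------------------------------------
    trimmed = [trim_lead(r, config.lead_s) for r in recordings]
    series: dict[tuple[str, str], pd.DataFrame] = {}
    for rec in trimmed:
        try:
            series[(rec.subject_id, rec.condition)] = pat.per_second_means(rec)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(
                f"per_second_means failed for {rec.subject_id}/{rec.condition}: {exc}"
            ) from exc

    n_subjects = len({sid for sid, _ in series})

    # --- patterns -----------------------------------------------------
    patterns: dict[str, pat.GroupPattern] = {}
    grids: dict[str, pd.DataFrame] = {}
    long_frames = []
    for cond in CONDITIONS:
        doms = {
            sid: pat.dominant_per_second(s)
            for (sid, c), s in series.items()
            if c == cond
        }
        gp = pat.group_percentages(doms, tl)
        patterns[cond] = gp
        grids[cond] = pat.interval_means(gp, tl)
        long_frames.append(pat.pattern_to_long(gp, cond))
        _write_table(grids[cond], outdir / f"interval_grid_{cond}.csv", cfg_hash)
        _write_table(
            pat.extremes_per_interval(grids[cond]),
            outdir / f"extremes_{cond}.csv",
            cfg_hash,
        )
    _write_table(
        pd.concat(long_frames, ignore_index=True),
        outdir / "pattern_per_second.csv",
        cfg_hash,
        index=False,
    )
    diff = pat.condition_difference(grids["exclusion"], grids["inclusion"])
    _write_table(diff, outdir / "difference_grid.csv", cfg_hash)

    # comparative-error screen of every interval contrast
    ce_rows = []
    for e in EMOTIONS:
        for i in tl.intervals:
            p_inc, p_exc = grids["inclusion"].loc[e, i], grids["exclusion"].loc[e, i]
            if np.isnan(p_inc) or np.isnan(p_exc):
                continue
            ce = pat.comparative_error(
                p_inc, p_exc, n_subjects, n_subjects, config.z_critical
            )
            ce_rows.append(
                {
                    "emotion": e,
                    "interval": i,
                    "p_inclusion": p_inc,
                    "p_exclusion": p_exc,
                    "diff": ce.diff,
                    "comparative_error": ce.ce,
                    "significant": ce.significant,
                }
            )
    _write_table(
        pd.DataFrame(ce_rows), outdir / "comparative_error.csv", cfg_hash, index=False
    )

    # --- shuffled white-noise null ------------------------------------
    null_frames = []
    for cond in CONDITIONS:
        gp = patterns[cond].complete_prefix
        rep = shuf.shuffle_and_compare(
            gp, _child_seed(config.seed, f"shuffle:{cond}"), k=config.shuffle_k
        )
        rep.insert(0, "condition", cond)
        null_frames.append(rep.reset_index())
    _write_table(
        pd.concat(null_frames, ignore_index=True),
        outdir / "shuffle_null.csv",
        cfg_hash,
        index=False,
    )

    # --- AUC / masking ------------------------------------------------
    auc_rows = []
    for (sid, cond), s in series.items():
        recs = auc.segment_aucs(s, tl)
        recs.insert(0, "subject", sid)
        recs.insert(1, "condition", cond)
        auc_rows.append(recs)
    auc_table = pd.concat(auc_rows, ignore_index=True)
    masked = auc.masked_auc(auc_table)
    props = auc.proportions(auc_table)
    _write_table(auc_table, outdir / "auc.csv", cfg_hash, index=False)
    _write_table(masked, outdir / "auc_masked.csv", cfg_hash, index=False)
    _write_table(props, outdir / "auc_proportions.csv", cfg_hash, index=False)

    # --- inference ----------------------------------------------------
    inference: dict = {}
    subjects = sorted({sid for sid, _ in series})

    def _total(e, cond):
        sub = auc_table[
            (auc_table["scope"] == "total")
            & (auc_table["emotion"] == e)
            & (auc_table["condition"] == cond)
        ]
        return sub.set_index("subject").loc[subjects, "auc"].to_numpy()

    wilcoxon = {}
    for e in EMOTIONS:
        try:
            res = inf.wilcoxon_paired(_total(e, "exclusion"), _total(e, "inclusion"))
            wilcoxon[e] = {"Z": res.value, "p": res.p, "note": res.note}
        except ValueError as exc:
            wilcoxon[e] = {"error": str(exc)}
    inference["wilcoxon_total_auc"] = wilcoxon

    masked_w = {}
    for e in [e for e in EMOTIONS if e != "happiness"]:
        msub = masked[(masked["scope"] == "total") & (masked["emotion"] == e)]
        piv = msub.pivot(index="subject", columns="condition", values="masked_auc")
        res = inf.wilcoxon_paired(
            piv.loc[subjects, "exclusion"].to_numpy(),
            piv.loc[subjects, "inclusion"].to_numpy(),
        )
        masked_w[e] = {"Z": res.value, "p": res.p, "note": res.note}
    inference["wilcoxon_masked_auc"] = masked_w

    seg_long = auc_table[auc_table["scope"] != "total"].copy()
    seg_long["segment"] = seg_long["scope"].str.removeprefix("segment").astype(int)
    try:
        anova = inf.rm_anova_2way(
            seg_long[["subject", "condition", "segment", "emotion", "auc"]],
            transforms=config.transforms,
            adjust=config.correction,
        )
        _write_table(anova, outdir / "rm_anova.csv", cfg_hash, index=False)
        inference["rm_anova"] = "rm_anova.csv"
    except ValueError as exc:
        logger.warning("rm_anova skipped: %s", exc)
        inference["rm_anova"] = f"skipped: {exc}"

    if scores is not None:
        x = scores["nts_exclusion"].to_numpy()
        y = scores["nts_inclusion"].to_numpy()
        try:
            t_res = inf.paired_t(x, y)
            inference["nts_paired_t"] = {
                "t": t_res.value,
                "df": t_res.df,
                "p": t_res.p,
                "mean_shift": float(np.mean(x - y)),
            }
        except ValueError as exc:
            inference["nts_paired_t"] = {"error": str(exc)}
        scale_cols = [
            c for c in ("scid_ii", "bis15", "best", "ders_e") if c in scores.columns
        ]
        if len(scores) >= 4 and scale_cols:
            mats = inf.spearman_matrix(scores[scale_cols])
            _write_table(mats["rho"], outdir / "scale_correlations.csv", cfg_hash)
            auc_wide = (
                auc_table[auc_table["scope"] == "total"]
                .pivot(index="subject", columns=["condition", "emotion"], values="auc")
            )
            auc_wide.columns = [f"{e}_{c}" for c, e in auc_wide.columns]
            merged_scales = scores.set_index("subject_id").loc[
                auc_wide.index, scale_cols
            ]
            cross = inf.spearman_matrix(merged_scales, auc_wide)
            _write_table(cross["rho"], outdir / "scale_auc_correlations.csv", cfg_hash)
            _write_table(
                cross["p_adjusted"], outdir / "scale_auc_p_adjusted.csv", cfg_hash
            )
            inference["scale_correlations"] = "scale_correlations.csv"

    (outdir / "inference.json").write_text(json.dumps(inference, indent=2))

    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("cyberface")
    except Exception:  # pragma: no cover - not installed as a distribution
        pkg_version = "unknown"
    report = {
        "version": pkg_version,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "mode": config.mode,
        "n_subjects": n_subjects,
        "n_recordings": len(series),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(report, indent=2))
    return report
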