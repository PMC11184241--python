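"""Inferential layer: paired tests, repeated-measures ANOVA, corrections.

The clinical side of the analysis relates expression summaries (AUCs) to
self-report scales: paired t for the post-condition Need Threat Scale,
Wilcoxon signed-rank tests between conditions, a two-way repeated-measures
ANOVA (condition x segment) per emotion with normality-restoring transforms
and a 3xIQR extreme-outlier screen, Benjamini-Hochberg or Bonferroni
multiplicity control, and Spearman correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .emotions import EMOTIONS


class DegenerateInputError(ValueError):
    """The data admit no test (e.g. constant nonzero paired differences)."""


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    value: float
    df: float | tuple[float, float] | None
    p: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    note: str | None = None


def paired_t(x, y) -> TestResult:
    """Classical paired t test (df = n - 1, two-sided)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("t", 0.0, len(x) - 1, 1.0, note="identical pairs")
        raise DegenerateInputError("constant nonzero differences: t undefined")
    t, p = stats.ttest_rel(x, y)
    return TestResult("t", float(t), len(x) - 1, float(p))


def wilcoxon_paired(x, y) -> TestResult:
    """Wilcoxon signed-rank test with a signed normal-approximation Z.

    Zero differences are dropped (Wilcoxon's original treatment) and ties
    mid-ranked with the usual variance correction.  ``Z`` is signed:
    positive when x tends to exceed y, and swapping the arguments negates
    it.  All-zero differences are degenerate: Z = 0, p = 1, flagged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("wilcoxon_paired needs two equal-length vectors")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("Z", 0.0, None, 1.0, note="all differences zero")
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0  # tie correction
    if var <= 0:
        return TestResult("Z", 0.0, None, 1.0, note="all |differences| tied at zero variance")
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult("Z", float(z), None, min(p, 1.0))


# --- normalizing transforms ------------------------------------------------

#: Per-emotion transform applied before the repeated-measures ANOVA, chosen
#: (per emotion) as the normalization that best restored Shapiro-Wilk
#: normality of the AUC distributions: inverse hyperbolic sine for anger,
#: happiness, sadness and surprise; rank-based ordered-quantile for fear;
#: Yeo-Johnson for disgust; contempt untransformed.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "happiness": "arcsinh",
    "sadness": "arcsinh",
    "anger": "arcsinh",
    "surprise": "arcsinh",
    "fear": "ordered-quantile",
    "disgust": "yeo-johnson",
    "contempt": "none",
}


def apply_transform(values, method: str) -> np.ndarray:
    """Apply a named normalizing transform to a vector.

    ``ordered-quantile`` maps mid-ranks through the standard normal
    quantile function, ``z_i = Phi^{-1}((r_i - 0.5) / n)``; ``yeo-johnson``
    fits its exponent by maximum likelihood on the vector itself.
    """
    v = np.asarray(values, float)
    if method == "none":
        return v
    if method == "arcsinh":
        return np.arcsinh(v)
    if method == "ordered-quantile":
        r = stats.rankdata(v, method="average")
        return stats.norm.ppf((r - 0.5) / len(v))
    if method == "yeo-johnson":
        out, _ = stats.yeojohnson(v)
        return np.asarray(out)
    raise ValueError(f"unknown transform {method!r}")


def identify_outliers(values) -> pd.DataFrame:
    """Flag extreme points outside [Q1 - 3*IQR, Q3 + 3*IQR].

    Quartiles use linear interpolation (numpy's default, R type-7).
    Returns a DataFrame with the flagged positions, values, the bound
    crossed and its threshold; empty when nothing is extreme.
    """
    v = pd.Series(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values to screen for outliers")
    q1, q3 = np.percentile(v.to_numpy(), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    flagged = v[(v < lo) | (v > hi)]
    return pd.DataFrame(
        {
            "index": flagged.index,
            "value": flagged.to_numpy(),
            "bound": np.where(flagged.to_numpy() > hi, "upper", "lower"),
            "threshold": np.where(flagged.to_numpy() > hi, hi, lo),
        }
    )


def adjust_pvalues(pvals, method: str = "benjamini-hochberg") -> np.ndarray:
    """Multiplicity-adjusted p-values (BH step-up or Bonferroni)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"benjamini-hochberg": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def rm_anova_2way(
    aucs: pd.DataFrame,
    transforms: dict[str, str] | None = None,
    include_outliers: bool = True,
    adjust: str = "benjamini-hochberg",
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA (condition x segment) per emotion.

    ``aucs`` is a long balanced table with columns subject, condition,
    segment, emotion, auc — one value per subject x condition x segment
    cell.  Each emotion's values are passed through its normalizing
    transform before fitting.  With ``include_outliers=False``, subjects
    contributing a point beyond the 3xIQR extreme bounds for that emotion
    are dropped whole (cells are never imputed, the design stays balanced).

    Returns one row per emotion x effect with DFn, DFd, F, p (uncorrected,
    matching integer df), the Greenhouse-Geisser corrected p, generalized
    eta-squared, a Shapiro-Wilk screen of the transformed values, and
    p_adjusted over the full emotion x effect family.
    """
    required = {"subject", "condition", "segment", "emotion", "auc"}
    if not required.issubset(aucs.columns):
        raise ValueError(f"aucs must have columns {sorted(required)}")
    transforms = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)
    rows = []
    for e in [e for e in EMOTIONS if e in set(aucs["emotion"])]:
        sub = aucs[aucs["emotion"] == e].copy()
        if not include_outliers:
            flagged = identify_outliers(sub["auc"].reset_index(drop=True))
            bad_subj = set(sub.iloc[flagged["index"]]["subject"]) if len(flagged) else set()
            sub = sub[~sub["subject"].isin(bad_subj)]
        pivot = sub.pivot_table(
            index="subject", columns=["condition", "segment"], values="auc"
        )
        if pivot.isna().any().any():
            raise ValueError(f"unbalanced design for {e}: missing cells")
        sub["y"] = apply_transform(sub["auc"].to_numpy(), transforms.get(e, "none"))
        sw_p = float(stats.shapiro(sub["y"]).pvalue) if sub["y"].std() > 0 else np.nan
        table = pg.rm_anova(
            data=sub, dv="y", within=["condition", "segment"],
            subject="subject", detailed=True, effsize="ng2",
        )
        for _, r in table.iterrows():
            effect = r["Source"].replace(" * ", ":")
            rows.append(
                {
                    "emotion": e,
                    "effect": effect,
                    "DFn": int(r["ddof1"]),
                    "DFd": int(r["ddof2"]),
                    "F": float(r["F"]),
                    "p": float(r["p_unc"]),
                    "p_GG": float(r["p_GG_corr"])
                    if "p_GG_corr" in table.columns
                    else np.nan,
                    "eta_sq": float(r["ng2"]),
                    "shapiro_p": sw_p,
                    "n_subjects": pivot.shape[0],
                    "transform": transforms.get(e, "none"),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), adjust)
    return out


def spearman_matrix(
    left: pd.DataFrame,
    right: pd.DataFrame | None = None,
    correction: str | None = "bonferroni",
) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman correlations with two-sided p and optional correction.

    With ``right=None`` the matrix is left vs itself (diagonal excluded from
    the correction family).  Constant columns yield NaN with a flag.
    Subjects (rows) must already be aligned; n >= 4 required.
    """
    symmetric = right is None
    right = left if symmetric else right
    if len(left) != len(right):
        raise ValueError("left and right must have aligned rows")
    if len(left) < 4:
        raise ValueError("need n >= 4 subjects for correlations")
    rho = pd.DataFrame(np.nan, index=left.columns, columns=right.columns)
    pmat = rho.copy()
    flags = []
    for a in left.columns:
        for b in right.columns:
            x, y = left[a].to_numpy(float), right[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                flags.append((a, b))
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[a, b], pmat.loc[a, b] = r, p
    padj = pmat.copy()
    if correction is not None:
        mask = ~pmat.isna()
        if symmetric:
            # adjust each unordered off-diagonal pair once
            iu = [(a, b) for i, a in enumerate(left.columns)
                  for b in list(right.columns)[i + 1:] if mask.loc[a, b]]
            vals = adjust_pvalues([pmat.loc[a, b] for a, b in iu], correction)
            for (a, b), v in zip(iu, vals):
                padj.loc[a, b] = padj.loc[b, a] = v
            for a in left.columns:
                padj.loc[a, a] = np.nan
        else:
            flat = pmat.to_numpy()[mask.to_numpy()]
            adj = adjust_pvalues(flat, correction)
            tmp = padj.to_numpy()
            tmp[mask.to_numpy()] = adj
            padj = pd.DataFrame(tmp, index=padj.index, columns=padj.columns)
    return {"rho": rho, "p": pmat, "p_adjusted": padj,
            "constant_pairs": pd.DataFrame(flags, columns=["left", "right"])}


@dataclass
class TransformSpec:
    """Per-emotion normalizing-transform assignment for the ANOVA stage."""

    mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORMS)
    )

    def __post_init__(self) -> None:
        allowed = {"arcsinh", "ordered-quantile", "yeo-johnson", "none"}
        bad = {m for m in self.mapping.values()} - allowed
        if bad:
            raise ValueError(f"unknown transform(s) {sorted(bad)}")
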