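"""White-noise null model: second-by-second shuffling of the group pattern.

The observed group pattern has temporal and identity structure: the same
emotions tend to dominate over stretches of seconds.  Permuting, within
every second independently, which emotion carries which percentage destroys
that structure while conserving each second's values — a white-noise
synthetic control.  Each emotion's original series is then compared with
its shuffled counterpart by a two-sample t test across seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .emotions import EMOTIONS, N_EMOTIONS
from .pattern_analysis import GroupPattern


@dataclass
class ShuffledPattern:
    source: GroupPattern
    shuffled: GroupPattern
    permutations: np.ndarray  # (n_seconds, 7) column indices
    seed: int


def shuffle_pattern(pattern: GroupPattern, seed: int) -> ShuffledPattern:
    """Permute each second's seven percentages with a fresh random permutation.

    Permutations are drawn per second by Fisher-Yates from a seeded PCG64
    generator, so results are reproducible across platforms.  The pattern
    must have no missing seconds; restrict to
    :attr:`GroupPattern.complete_prefix` first if it does.
    """
    pct = pattern.percentages
    if pct.isna().any().any():
        raise ValueError(
            "pattern has missing seconds; shuffle the complete prefix "
            "(GroupPattern.complete_prefix) or restrict the timeline"
        )
    rng = np.random.default_rng(seed)
    n = len(pct)
    perms = rng.permuted(
        np.tile(np.arange(N_EMOTIONS), (n, 1)), axis=1
    )
    vals = pct.to_numpy(float)
    shuffled = np.take_along_axis(vals, perms, axis=1)
    shuf_df = pd.DataFrame(shuffled, index=pct.index, columns=pct.columns)
    return ShuffledPattern(
        source=pattern,
        shuffled=GroupPattern(shuf_df, pattern.n_subjects.copy()),
        permutations=perms,
        seed=seed,
    )


def compare_to_null(
    source: GroupPattern,
    shuffled: GroupPattern,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-emotion t test of the original series against its shuffle.

    ``variant`` selects Student's pooled-variance two-sample t (default),
    Welch's unequal-variance t, or a paired t across seconds.  Returns one
    row per emotion with t, two-sided p, n_seconds and a ``degenerate``
    flag (both series constant: t is reported as 0 with p = 1).
    """
    a = source.percentages
    b = shuffled.percentages
    if len(a) != len(b):
        raise ValueError("source and shuffled patterns differ in length")
    rows = []
    for e in EMOTIONS:
        x, y = a[e].to_numpy(float), b[e].to_numpy(float)
        degenerate = x.std() < 1e-12 and y.std() < 1e-12
        if degenerate and np.allclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        elif variant == "student":
            t, p = stats.ttest_ind(x, y, equal_var=True)
        elif variant == "welch":
            t, p = stats.ttest_ind(x, y, equal_var=False)
        elif variant == "paired":
            t, p = stats.ttest_rel(x, y)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        rows.append(
            {
                "emotion": e,
                "t": float(t),
                "p": float(p),
                "n_seconds": len(x),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows).set_index("emotion")


def shuffle_and_compare(
    pattern: GroupPattern,
    seed: int,
    k: int = 1,
    variant: str = "student",
) -> pd.DataFrame:
    """Run ``k`` independent shuffle realizations and summarize.

    With ``k = 1`` (the default, mirroring a single synthetic-control
    realization) the result is a plain comparison table; with ``k > 1`` the
    per-emotion t and p are medians over realizations, with the spread
    reported alongside for stability checks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        out = compare_to_null(pattern, shuffle_pattern(pattern, seed).shuffled, variant)
        out["seed"] = seed
        return out
    reps = []
    child_seeds = np.random.SeedSequence(seed).generate_state(k)
    for s in child_seeds:
        rep = compare_to_null(
            pattern, shuffle_pattern(pattern, int(s) % 2**31).shuffled, variant
        )
        reps.append(rep[["t", "p"]])
    stacked = pd.concat(reps, keys=range(k))
    med = stacked.groupby(level=1).median()
    spread = stacked.groupby(level=1)["t"].std().rename("t_sd")
    out = med.join(spread)
    out["n_seconds"] = len(pattern.percentages)
    out["k"] = k
    out["seed"] = seed
    return out.loc[list(EMOTIONS)]
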