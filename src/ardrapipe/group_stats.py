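"""Compartment-effect inference: one-way repeated-measures ANOVA with fish
as the subject factor, Tukey multiple comparisons on the studentized range
distribution, and compact-letter displays.

The design is a complete balanced subjects x levels matrix (fish x gut
compartments).  The within-subject ANOVA removes the between-fish sum of
squares before testing the compartment effect:

    F = MS_treatment / MS_error,  df = (k - 1, (k - 1)(n - 1))

No sphericity correction is applied (recorded in the result metadata).  For
proportion responses an arcsine-square-root transform is available, since
raw proportions violate the normality assumption near 0 and 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "rm_anova",
    "tukey_letters",
    "rm_anova_with_tukey",
    "arcsine_sqrt",
    "friedman",
]


def arcsine_sqrt(proportions: np.ndarray | Sequence[float]) -> np.ndarray:
    """Arcsine-square-root variance-stabilizing transform for proportions
    given either as fractions in [0, 1] or percentages in [0, 100]."""
    p = np.asarray(proportions, dtype=float)
    if (p > 1.0).any():
        p = p / 100.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1] (or [0, 100] as %)")
    return np.arcsin(np.sqrt(p))


def _validate_design(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("design must be a 2-D subjects x levels matrix")
    if np.isnan(x).any():
        raise ValueError("design has missing cells; a complete balanced "
                         "design is required")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for a within-subject ANOVA")
    if k < 2:
        raise ValueError("need at least 2 levels")
    return x


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA summary, optionally with Tukey comparisons."""

    F: float
    df_treatment: int
    df_error: int
    p: float
    ms_error: float
    level_means: pd.Series
    n_subjects: int
    ss_subjects: float
    ss_treatment: float
    ss_error: float
    sphericity_correction: str = "none"
    tukey: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def rm_anova(data: np.ndarray | pd.DataFrame,
             level_labels: Sequence[str] | None = None) -> AnovaResult:
    """One-way within-subject ANOVA on a subjects x levels response matrix.

    Rows are subjects (fish), columns the repeated levels (compartments).
    The between-subject sum of squares is removed; the treatment effect is
    tested against the subject x treatment interaction (the error term of
    the repeated-measures layout).
    """
    if isinstance(data, pd.DataFrame):
        if level_labels is None:
            level_labels = [str(c) for c in data.columns]
        data = data.values
    x = _validate_design(data)
    n, k = x.shape
    if level_labels is None:
        level_labels = [f"L{i + 1}" for i in range(k)]

    grand = x.mean()
    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)
    ss_subjects = k * float(((subj_means - grand) ** 2).sum())
    ss_treatment = n * float(((level_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_treatment

    df_t = k - 1
    df_e = (k - 1) * (n - 1)
    ms_t = ss_treatment / df_t
    ms_e = ss_error / df_e
    if ms_e <= 0:
        # zero residual variance: F is 0/0 if the treatment SS is also zero,
        # infinite otherwise
        f_stat = 0.0 if ss_treatment <= 1e-12 else math.inf
        p = 1.0 if ss_treatment <= 1e-12 else 0.0
    else:
        f_stat = ms_t / ms_e
        p = float(stats.f.sf(f_stat, df_t, df_e))
    return AnovaResult(
        F=float(f_stat), df_treatment=df_t, df_error=df_e, p=p,
        ms_error=float(ms_e),
        level_means=pd.Series(level_means, index=list(level_labels)),
        n_subjects=n, ss_subjects=ss_subjects, ss_treatment=ss_treatment,
        ss_error=ss_error,
    )


def _compact_letters(levels: Sequence[str],
                     significant: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    Two levels share a letter iff their pair is *not* in ``significant``.
    """
    letter_sets: list[set[str]] = [set(levels)]
    for pair in sorted(significant, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb sets contained in another set; dedupe
        new_sets = [s for s in new_sets if s]
        kept: list[set[str]] = []
        for s in new_sets:
            if any(s < t for t in new_sets):
                continue
            if s not in kept:
                kept.append(s)
        letter_sets = kept
    # deterministic letter order: by first member in level order
    order = {lev: i for i, lev in enumerate(levels)}
    letter_sets.sort(key=lambda s: (min(order[m] for m in s),
                                    -len(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for i, s in enumerate(letter_sets):
        for lev in levels:
            if lev in s:
                out[lev] += alphabet[i % len(alphabet)]
    return out


def tukey_letters(level_means: Mapping[str, float] | pd.Series,
                  ms_error: float, df_error: int, n_per_level: int,
                  alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey all-pairs comparisons with a compact-letter display.

    The studentized-range statistic for levels i, j is
    ``q = |mean_i - mean_j| / sqrt(MS_error / n)``; adjusted p-values come
    from the studentized range distribution with (k, df_error).  Levels
    share a letter iff their adjusted p >= alpha.

    Returns ``(pairs, letters)`` where ``pairs`` has one row per level pair
    with the q statistic and adjusted p.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1 for Tukey comparisons")
    if ms_error < 0:
        raise ValueError("MS_error must be >= 0")
    means = pd.Series(level_means, dtype=float)
    levels = list(means.index)
    k = len(levels)
    se = math.sqrt(ms_error / n_per_level) if ms_error > 0 else 0.0
    rows = []
    significant: set[frozenset[str]] = set()
    for a, b in combinations(levels, 2):
        diff = abs(means[a] - means[b])
        if se > 0:
            q = diff / se
            p_adj = float(stats.studentized_range.sf(q, k, df_error))
        else:
            q = 0.0 if diff <= 1e-12 else math.inf
            p_adj = 1.0 if diff <= 1e-12 else 0.0
        rows.append({"level_a": a, "level_b": b, "mean_diff": means[a] - means[b],
                     "q": q, "p_adj": min(p_adj, 1.0)})
        if p_adj < alpha:
            significant.add(frozenset((a, b)))
    pairs = pd.DataFrame(rows)
    return pairs, _compact_letters(levels, significant)


def rm_anova_with_tukey(data: pd.DataFrame | np.ndarray,
                        level_labels: Sequence[str] | None = None,
                        alpha: float = 0.05) -> AnovaResult:
    """Repeated-measures ANOVA followed by Tukey letters on the same data."""
    res = rm_anova(data, level_labels)
    pairs, letters = tukey_letters(res.level_means, res.ms_error,
                                   res.df_error, res.n_subjects, alpha=alpha)
    res.tukey = pairs
    res.letters = letters
    return res


def friedman(data: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Non-parametric alternative (Friedman test) on the same layout; thin
    wrapper kept for completeness."""
    if isinstance(data, pd.DataFrame):
        data = data.values
    x = _validate_design(data)
    stat, p = stats.friedmanchisquare(*[x[:, j] for j in range(x.shape[1])])
    return float(stat), float(p)
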