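"""Per-library richness, coverage, rarefaction and diversity statistics.

All statistics operate on integer OTU counts from one clone library.  A note
on symbols, which are overloaded in the classical formulas: here ``N`` is
always the total number of clones in the library, ``count_i`` the number of
clones of OTU *i*, ``F1`` the number of singleton OTUs (count 1) and ``F2``
the number of doubletons (count 2).

Implemented estimators:

* Good's coverage:       C% = (1 - F1/N) * 100
* Chao1 richness:        S_obs + F1^2 / (2 F2), with the bias-corrected form
                         S_obs + F1(F1-1) / (2(F2+1)) available (and used
                         automatically when F2 = 0); 95% CI by the log-normal
                         method on the estimated number of unseen OTUs.
* Analytic rarefaction:  E[S_d] = sum_i (1 - C(N-count_i, d)/C(N, d)),
                         hypergeometric expectation with the exact variance
                         (covariance form), no resampling.
* Shannon H' (nats):     -sum p_i ln p_i
* Simpson reciprocal:    1 / sum p_i^2
* Evenness:              H' / log_b(S); base e gives Pielou's J (<= 1), the
                         base-10 mode divides nats by log10(S), a historical
                         convention under which values exceed 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "OTUTable",
    "goods_coverage",
    "chao_richness",
    "rarefy",
    "rarefaction_curve",
    "shannon",
    "simpson_reciprocal",
    "evenness",
    "diversity_report",
]


def _as_counts(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("counts are empty")
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(int)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("counts must contain at least one positive value")
    return c


@dataclass(frozen=True)
class OTUTable:
    """Libraries x OTUs count matrix.

    Rows are library labels of the form ``"<fish>|<compartment>"``; columns
    are OTU ids.  Construction drops all-zero OTU columns and validates
    non-negative integer counts.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if (df.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not np.allclose(df.values, np.round(df.values)):
            raise ValueError("OTU counts must be integers")
        df = df.loc[:, df.sum(axis=0) > 0].astype(int)
        object.__setattr__(self, "counts", df)

    @classmethod
    def from_assignments(cls, assignments: Mapping[str, str],
                         clone_library: Mapping[str, str]) -> "OTUTable":
        """Build from clone -> OTU and clone -> library label maps."""
        df = pd.DataFrame({
            "library": [clone_library[c] for c in assignments],
            "otu": list(assignments.values()),
        })
        table = (df.groupby(["library", "otu"]).size().unstack(fill_value=0)
                 .sort_index())
        table = table[sorted(table.columns)]
        table.index.name = "library"
        return cls(counts=table)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_counts(self, library: str) -> np.ndarray:
        row = self.counts.loc[library].values
        return row[row > 0]

    def incidence(self, library: str) -> set[str]:
        row = self.counts.loc[library]
        return set(row.index[row > 0])

    def library_size(self, library: str) -> int:
        return int(self.counts.loc[library].sum())


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage, percent: ``(1 - F1/N) * 100``.

    A coverage of 99% means one new OTU is expected per 100 further clones.
    """
    c = _as_counts(counts)
    n_singletons = int((c == 1).sum())
    total = int(c.sum())
    return 100.0 * (1.0 - n_singletons / total)


def chao_richness(counts: Sequence[int],
                  bias_corrected: bool = False) -> tuple[float, float, float]:
    """Chao1 richness estimate with a 95% log-normal confidence interval.

    The classic estimator ``S_obs + F1^2/(2 F2)`` is the default; when
    ``F2 = 0`` (or when ``bias_corrected=True``) the bias-corrected form
    ``S_obs + F1(F1-1)/(2(F2+1))`` is used.  The CI places a log-normal
    distribution on the estimated number of unseen OTUs ``T = est - S_obs``
    (the convention of the EstimateS program), so the lower bound never
    falls below ``S_obs``.

    Returns ``(estimate, ci_low, ci_high)``.
    """
    c = _as_counts(counts)
    s_obs = int(c.size)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())

    if f1 == 0:
        return float(s_obs), float(s_obs), float(s_obs)

    if bias_corrected or f2 == 0:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        var = (f1 * (f1 - 1) / (2.0 * (f2 + 1))
               + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
               + f1 ** 2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4))
    else:
        r = f1 / f2
        est = s_obs + f1 ** 2 / (2.0 * f2)
        var = f2 * (r ** 2 / 2.0 + r ** 3 + r ** 4 / 4.0)

    t = est - s_obs
    if t <= 0 or var <= 0:
        return float(est), float(s_obs), float(max(est, s_obs))
    k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / t ** 2)))
    return float(est), float(s_obs + t / k), float(s_obs + t * k)


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(
        np.asarray(n) - k + 1)


def rarefy(counts: Sequence[int], depth: int) -> tuple[float, float]:
    """Analytic (hypergeometric) rarefaction at one depth.

    Expected richness in a uniform random subsample of ``depth`` clones:
    ``E[S_d] = sum_i [1 - C(N - count_i, d) / C(N, d)]``, with the exact
    variance including the pairwise covariance terms.  Binomial coefficients
    are evaluated in log-gamma space, so any ``N`` is safe.

    Returns ``(expected_S, variance)``.
    """
    c = _as_counts(counts)
    total = int(c.sum())
    if not 1 <= depth <= total:
        raise ValueError(f"depth must be in [1, {total}], got {depth}")
    log_cnd = _log_choose(float(total), float(depth))

    def q(missing_pool: np.ndarray) -> np.ndarray:
        """P(a pool of size N - x contributes all d draws) = C(N-x, d)/C(N, d)."""
        pool = np.asarray(missing_pool, dtype=float)
        out = np.zeros_like(pool)
        ok = pool >= depth
        out[ok] = np.exp(_log_choose(pool[ok], float(depth)) - log_cnd)
        return out

    qi = q(total - c)                      # P(OTU i absent from subsample)
    expected = float(np.sum(1.0 - qi))
    var = float(np.sum(qi * (1.0 - qi)))
    # covariance terms: P(both i and j absent) - P(i absent) P(j absent)
    if c.size > 1:
        pair_pool = (total - c[:, None] - c[None, :]).astype(float)
        qij = q(pair_pool)
        cov = qij - qi[:, None] * qi[None, :]
        var += float(cov.sum() - np.trace(cov))
    return expected, max(var, 0.0)


def rarefaction_curve(counts: Sequence[int],
                      depths: Sequence[int] | None = None) -> pd.DataFrame:
    """Rarefaction curve with 95% CIs, clamped to ``[0, S_obs]``.

    Returns a DataFrame with columns depth, expected_S, variance, ci95_low,
    ci95_high.  Defaults to every depth ``1..N``.
    """
    c = _as_counts(counts)
    total = int(c.sum())
    s_obs = int(c.size)
    if depths is None:
        depths = range(1, total + 1)
    rows = []
    for d in depths:
        e, v = rarefy(c, int(d))
        half = 1.96 * math.sqrt(v)
        rows.append({
            "depth": int(d), "expected_S": e, "variance": v,
            "ci95_low": max(e - half, 0.0),
            "ci95_high": min(e + half, float(s_obs)),
        })
    return pd.DataFrame(rows)


def shannon(counts: Sequence[int]) -> float:
    """Shannon diversity H' in nats: ``-sum p_i ln p_i``."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson_reciprocal(counts: Sequence[int]) -> float:
    """Simpson reciprocal diversity 1/D with ``D = sum p_i^2``."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(1.0 / (p ** 2).sum())


def evenness(h_prime: float, s: int, log_base: float = math.e) -> float:
    """Evenness E = H' / log_b(S).

    With base e this is Pielou's J and is bounded by 1; with base 10 it
    reproduces the historical convention of dividing H' in nats by log10(S),
    under which values above 1 are routine.
    """
    if s < 2:
        raise ValueError("evenness is undefined for S < 2 (log S = 0)")
    return float(h_prime / (math.log(s) / math.log(log_base)))


def diversity_report(table: OTUTable, chao_variant: str = "classic",
                     evenness_base: float = math.e) -> pd.DataFrame:
    """Full per-library diversity report.

    One row per library: S_obs, Good's coverage (%), Chao1 estimate and 95%
    CI, Shannon H' (nats), Simpson 1/D, evenness (NaN when S_obs < 2),
    singleton and doubleton counts, and N.
    """
    if chao_variant not in ("classic", "bias-corrected"):
        raise ValueError(f"unknown Chao variant {chao_variant!r}")
    rows = []
    for lib in table.libraries:
        c = table.library_counts(lib)
        h = shannon(c)
        s_obs = int(c.size)
        est, lo, hi = chao_richness(c, bias_corrected=(
            chao_variant == "bias-corrected"))
        rows.append({
            "library": lib,
            "N": int(c.sum()),
            "S_obs": s_obs,
            "F1": int((c == 1).sum()),
            "F2": int((c == 2).sum()),
            "coverage_pct": goods_coverage(c),
            "chao_est": est,
            "chao_ci_low": lo,
            "chao_ci_high": hi,
            "shannon_H": h,
            "simpson_recip": simpson_reciprocal(c),
            "evenness_E": (evenness(h, s_obs, evenness_base)
                           if s_obs >= 2 else float("nan")),
        })
    df = pd.DataFrame(rows).set_index("library")
    df.attrs["chao_variant"] = chao_variant
    df.attrs["evenness_base"] = evenness_base
    return df
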