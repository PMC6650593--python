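"""Time-lagged local similarity analysis (LSA) for short monthly series.

The LS statistic finds the best contiguous, possibly time-shifted segment
over which two series co-vary.  Series are first gap-filled by linear
interpolation and rank-normalized to normal scores; two dynamic programs
then maximize the positive and negative partial sums of products over all
alignments with offset at most ``D`` months.  Significance is assessed by a
permutation test (the time order of one series is shuffled).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datamodel import SeriesSet

__all__ = [
    "PreparedSeries",
    "Association",
    "interpolate_series",
    "normal_score_transform",
    "prepare_series",
    "local_similarity_score",
    "permutation_p_value",
    "all_pairs_lsa",
]


@dataclass
class PreparedSeries:
    """A gap-free, normal-scored series ready for the LS dynamic program."""

    feature_id: str
    values: np.ndarray
    interpolated_mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class Association:
    """One scored, signed, possibly delayed pair.

    ``delay`` is in months; positive means ``feature_b`` lags ``feature_a``.
    Alignment start indices are 1-based; ``align_length`` is the number of
    consecutive months in the chain attaining the maximum.
    """

    feature_a: str
    feature_b: str
    ls: float
    sign: str  # "+" or "-"
    delay: int
    align_start_a: int
    align_start_b: int
    align_length: int
    p_value: float | None = None
    q_value: float | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.feature_a, self.feature_b)))


# ----------------------------------------------------------------------
# Series preparation
# ----------------------------------------------------------------------

def interpolate_series(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN gaps: linear interpolation inside, nearest value at the ends.

    Returns the filled vector and a boolean mask of the filled positions.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isnan(values)
    observed = np.flatnonzero(~mask)
    if observed.size < 2:
        raise ValueError("need at least 2 observed time points to interpolate")
    idx = np.arange(values.size)
    # np.interp holds the first/last observed value beyond the ends,
    # i.e. nearest-fill for leading/trailing gaps.
    filled = np.interp(idx, observed, values[observed])
    return filled, mask


def normal_score_transform(values: np.ndarray) -> np.ndarray:
    """Map values to normal scores Phi^-1(rank/(n+1)), average rank for ties."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = rankdata(values, method="average")
    return ndtri(ranks / (n + 1.0))


def prepare_series(feature_id: str, raw: np.ndarray) -> PreparedSeries:
    """Interpolate then normal-score one raw (possibly gappy) series."""
    filled, mask = interpolate_series(raw)
    return PreparedSeries(feature_id, normal_score_transform(filled), mask)


# ----------------------------------------------------------------------
# Dynamic program
# ----------------------------------------------------------------------

def _dp_best(x: np.ndarray, y: np.ndarray, D: int):
    """Banded DP over positive and negative partial sums with traceback.

    Returns (raw_score, sign, delay, start_a, start_b, length); the raw
    score is the un-normalized max partial sum.  Ties are broken by smaller
    |delay|, then positive sign, then earliest start.
    """
    n = x.size
    P = np.zeros((n + 1, n + 1))
    N = np.zeros((n + 1, n + 1))
    LP = np.zeros((n + 1, n + 1), dtype=int)
    LN = np.zeros((n + 1, n + 1), dtype=int)
    best = 0.0
    best_key = None
    best_info = (0.0, "+", 0, 1, 1, 0)
    for i in range(1, n + 1):
        lo = max(1, i - D)
        hi = min(n, i + D)
        for j in range(lo, hi + 1):
            prod = x[i - 1] * y[j - 1]
            v = P[i - 1, j - 1] + prod
            if v > 0:
                P[i, j] = v
                LP[i, j] = LP[i - 1, j - 1] + 1
            w = N[i - 1, j - 1] - prod
            if w > 0:
                N[i, j] = w
                LN[i, j] = LN[i - 1, j - 1] + 1
            for score, sign, length in ((v, "+", LP[i, j]), (w, "-", LN[i, j])):
                if score <= 0 or score < best:
                    continue
                delay = j - i
                key = (abs(delay), 0 if sign == "+" else 1,
                       i - length + 1, j - length + 1)
                if score > best or (score == best and key < best_key):
                    best = score
                    best_key = key
                    best_info = (score, sign, delay,
                                 i - length + 1, j - length + 1, length)
    return best_info


def local_similarity_score(
    x: PreparedSeries, y: PreparedSeries, D: int = 1
) -> Association:
    """LS score of two prepared series; no p-value attached.

    LS = (max partial sum over the banded alignments)/n, non-negative;
    the sign records whether the positive or negative program attained it.
    """
    if x.n != y.n:
        raise ValueError("series lengths differ")
    if D < 0 or D >= x.n:
        raise ValueError("delay limit D must satisfy 0 <= D < n")
    score, sign, delay, sa, sb, length = _dp_best(x.values, y.values, D)
    return Association(
        x.feature_id, y.feature_id, score / x.n, sign, delay, sa, sb, length
    )


def _perm_scores(x: np.ndarray, Y: np.ndarray, D: int) -> np.ndarray:
    """Raw LS magnitude for x against every row of Y, vectorized over rows.

    Each band diagonal is an independent 1-D chain, so the DP runs as
    (2D+1) * n vectorized max/add steps over the permutation axis.
    """
    R, n = Y.shape
    best = np.zeros(R)
    for d in range(-D, D + 1):
        P = np.zeros(R)
        N = np.zeros(R)
        for i in range(max(1, 1 - d), min(n, n - d) + 1):
            prod = x[i - 1] * Y[:, i + d - 1]
            P = np.maximum(0.0, P + prod)
            N = np.maximum(0.0, N - prod)
            np.maximum(best, P, out=best)
            np.maximum(best, N, out=best)
    return best


def permutation_p_value(
    x: PreparedSeries,
    y: PreparedSeries,
    D: int = 1,
    n_perm: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    alpha: float | None = None,
) -> float:
    """Permutation p for the LS score: shuffle y's time order, x fixed.

    Add-one estimator p = (1 + #{LS_perm >= LS_obs}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1); a warning is raised when that
    floor cannot reach a requested ``alpha``.
    """
    if alpha is not None and 1.0 / (n_perm + 1) >= alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot attain p < {alpha}; "
            f"minimum p is {1.0 / (n_perm + 1):.4g}"
        )
    obs = local_similarity_score(x, y, D).ls * x.n
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, y.n)), axis=1)
    scores = _perm_scores(x.values, y.values[perms], D)
    # tiny float slop so identical alignments count as ties, not wins
    return (1.0 + int((scores >= obs - 1e-12).sum())) / (1.0 + n_perm)


def _pair_seed(seed: int, a: str, b: str) -> np.random.SeedSequence:
    """Stable per-pair seed, independent of pair enumeration order."""
    return np.random.SeedSequence([int(seed), zlib.crc32(f"{min(a,b)}|{max(a,b)}".encode())])


def all_pairs_lsa(
    series: SeriesSet,
    D: int = 1,
    n_perm: int = 2000,
    seed: int = 0,
    features: list[str] | None = None,
    alpha: float | None = None,
) -> list[Association]:
    """LS score + permutation p for every unordered feature pair of one series set.

    OTUs and environmental variables are treated alike.  Per-pair random
    streams are derived from the pair identity, so the result set does not
    depend on enumeration order.
    """
    table = series.table
    feats = sorted(features if features is not None else table.features)
    # place observed values onto the full month grid so gaps interpolate
    months = pd.period_range(series.dates[0], series.dates[-1], freq="M")
    pos = {str(m): k for k, m in enumerate(months)}
    prepared = {}
    for f in feats:
        raw = np.full(len(months), np.nan)
        for key, v in zip(series.dates, table.data[f].to_numpy()):
            raw[pos[key]] = v
        prepared[f] = prepare_series(f, raw)
    out = []
    for a, b in combinations(feats, 2):
        assoc = local_similarity_score(prepared[a], prepared[b], D)
        assoc.p_value = permutation_p_value(
            prepared[a], prepared[b], D, n_perm, _pair_seed(seed, a, b), alpha
        )
        out.append(assoc)
    return out
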