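"""The ranked-list enrichment statistic.

Given a word's per-gene log-scores ls_1..ls_u in ranked order, the
running sum of mean-centered scores

    r_0 = 0,   r_i = r_{i-1} + (ls_i - mean(ls))

starts and ends at zero, so under random permutation of the scores it
behaves like a Brownian bridge.  The maximum absolute deviation
D = max_i |r_i| is therefore tested against the two-sided Brownian-bridge
max distribution (the Kolmogorov distribution after scaling): with
x = D / (sigma * sqrt(t)), where sigma is the standard deviation of the
log-score set and t the number of genes,

    P(Y >= D/sigma) ~= 1 - sum_{h=-inf}^{inf} (-1)^h exp(-2 h^2 x^2).

For ranking words of different lengths on a common scale, D/sigma is
moment-normalized using the closed forms

    E[Y] = sqrt(pi t / 2) * ln 2,      Var[Y] = t pi^2 / 12 - E[Y]^2,

giving an approximately standard-normal Z per word.  The gene rank at
which |r| attains its global maximum is the enrichment specificity (ES)
index: a low ES index means the signal is concentrated in the most
strongly regulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .wordstats import LogScoreSet

__all__ = [
    "EnrichmentProfile",
    "WordResult",
    "running_sum",
    "bridge_max_sf",
    "bridge_moments",
    "z_score",
    "analyze_all_words",
]

DIRECTION_DOWN = "down"  # enriched among most down-regulated genes
DIRECTION_UP = "up"

# Below x = D/(sigma*sqrt(t)) = 0.05 the alternating series converges too
# slowly to be useful and such words are never significant; report p = 1.
SERIES_GUARD_X = 0.05
_SERIES_MAX_H = 1000


@dataclass(frozen=True)
class EnrichmentProfile:
    """Running-sum profile of one word over the ranked gene list.

    ``r`` has length u+1 with r[0] = 0 and r[u] = 0 (to rounding);
    ``D = max|r|``; ``es_index`` is the (1-based) gene rank attaining that
    maximum, smallest such rank on ties; ``direction`` is "down" when the
    maximum deviation is positive (scores concentrated early in the list,
    i.e. among down-regulated genes) and "up" otherwise.  ``degenerate``
    marks an all-constant score set (sigma = 0), which carries no signal.
    """

    word: str
    r: np.ndarray
    sigma: float
    D: float
    es_index: int
    direction: str
    degenerate: bool = False

    @property
    def u(self) -> int:
        return len(self.r) - 1


@dataclass(frozen=True)
class WordResult:
    """Summary statistics for one word (one row of the results table)."""

    word: str
    length: int
    total_occurrences: int
    n_genes_with_word: int
    D: float
    sigma: float
    es_index: int
    direction: str
    p_analytic: float
    z: float
    fdr: float
    rank: int


def running_sum(scores: LogScoreSet) -> EnrichmentProfile:
    """Build the mean-centered running sum and its max-deviation statistics.

    sigma is the population (1/u) standard deviation of the log-scores.
    A constant score set is flagged degenerate (D = 0, no direction
    preference; callers assign p = 1, z = 0).
    """
    ls = np.asarray(scores.scores, dtype=float)
    u = len(ls)
    if u < 2:
        raise ValueError("need at least 2 genes")
    r = np.empty(u + 1)
    r[0] = 0.0
    np.cumsum(ls - ls.mean(), out=r[1:])
    sigma = float(ls.std())  # population std
    abs_r = np.abs(r)
    idx = int(np.argmax(abs_r))  # first index attaining the max
    D = float(abs_r[idx])
    # constant score sets carry no signal; check exactly, since the
    # computed sigma of a constant vector can be rounding noise (~1e-20)
    if sigma == 0.0 or ls.max() == ls.min():
        return EnrichmentProfile(
            word=scores.word, r=r, sigma=0.0, D=0.0, es_index=1,
            direction=DIRECTION_DOWN, degenerate=True,
        )
    direction = DIRECTION_DOWN if r[idx] > 0 else DIRECTION_UP
    return EnrichmentProfile(
        word=scores.word, r=r, sigma=sigma, D=D,
        es_index=max(idx, 1), direction=direction,
    )


def bridge_max_sf(D: float, sigma: float, t: int, tol: float = 1e-12) -> float:
    """Survival probability of the Brownian-bridge absolute maximum.

    Evaluates ``1 - sum_h (-1)^h exp(-2 h^2 D^2 / (sigma^2 t))`` by
    symmetric truncation of the alternating series once terms drop below
    ``tol`` (hard cap |h| <= 1000).  For x = D/(sigma*sqrt(t)) below
    0.05 returns 1.0 (series guard); strictly decreasing in D above it.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0 (handle degenerate words upstream)")
    if t < 2:
        raise ValueError("t must be >= 2")
    if D < 0:
        raise ValueError("D must be >= 0")
    x = D / (sigma * math.sqrt(t))
    return _series_sf(x, tol)


def _series_sf(x: float, tol: float = 1e-12) -> float:
    if x < SERIES_GUARD_X:
        return 1.0
    # 1 - K(x) = 2 * sum_{h>=1} (-1)^(h+1) exp(-2 h^2 x^2)
    acc = 0.0
    for h in range(1, _SERIES_MAX_H + 1):
        term = math.exp(-2.0 * h * h * x * x)
        acc += term if h % 2 else -term
        if term < tol:
            break
    return min(max(2.0 * acc, 0.0), 1.0)


def _series_sf_vec(x: np.ndarray, n_terms: int = 120) -> np.ndarray:
    """Vectorized series; matches :func:`_series_sf` to <1e-12 for x >= 0.05."""
    x = np.asarray(x, dtype=float)
    h = np.arange(1, n_terms + 1)
    signs = np.where(h % 2 == 1, 1.0, -1.0)
    with np.errstate(under="ignore"):
        terms = np.exp(-2.0 * np.outer(x * x, h * h))
    sf = 2.0 * (terms * signs).sum(axis=1)
    sf = np.clip(sf, 0.0, 1.0)
    sf[x < SERIES_GUARD_X] = 1.0
    return sf


def bridge_moments(t: int) -> tuple[float, float]:
    """Mean and variance of the bridge-max statistic Y for t genes.

    ``E[Y] = sqrt(pi t / 2) ln 2`` and ``Var[Y] = t pi^2/12 - E[Y]^2``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    mean = math.sqrt(math.pi * t / 2.0) * math.log(2.0)
    var = t * math.pi**2 / 12.0 - mean**2
    return mean, var


def z_score(D: float, sigma: float, t: int) -> float:
    """Moment-normalized statistic Z = (D/sigma - E[Y]) / sqrt(Var[Y]).

    Identical to normalizing D against X = sigma*Y, since sigma cancels.
    Degenerate words (sigma = 0) get Z = 0.
    """
    if sigma <= 0:
        return 0.0
    mean, var = bridge_moments(t)
    return (D / sigma - mean) / math.sqrt(var)


def analyze_all_words(
    dataset,
    lengths: Iterable[int] = (6, 7, 8),
    order: int = 1,
    alpha: float = 1e-5,
    pseudocount: float = 1.0,
    workers: int = 1,
):
    """Exhaustive word analysis over a ranked dataset.

    Scores every word of every requested length in every gene, builds the
    running-sum statistic per word, and returns the pooled results table
    sorted by Z (see :meth:`wordbridge.model.WordEnrichment.fit` for the
    object-oriented entry point).  Output is bit-identical for any
    ``workers >= 1``.

    Returns
    -------
    pandas.DataFrame
        One row per word: word, length, total_occurrences,
        n_genes_with_word, D, sigma, es_index, direction, p_analytic, z,
        fdr, rank.
    """
    from .model import WordEnrichment

    model = WordEnrichment(
        dataset, lengths=lengths, order=order, alpha=alpha,
        pseudocount=pseudocount,
    )
    return model.fit(workers=workers).results
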