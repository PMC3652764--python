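"""Position-based features: interval-distance statistics per element.

For an element d (H, E or C), the occurrence positions Po(d) of d in a
sequence are differenced to give the interval distances Dis(d) between
successive occurrences (a distance of 1 means both residues lie in the
same segment).  The empirical distribution of those distances is summarized
by a truncated ("semi-") mean and variance,

    Semi-E_k = sum_{n<=k} n P(n),
    Semi-D_k = sum_{n<=k} n^2 P(n) - Semi-E_k^2,

computed WITHOUT renormalizing the truncated probabilities — they are not
the mean and variance unless k covers every observed distance.  The feature

    C_k = Semi-E_k / sqrt(Semi-D_k)

is the reciprocal coefficient of variation of the (truncated) distance
distribution; ``k=None`` (the "full" setting, written C_F) sums over all
observed distances.  When the variance is zero or fewer than two
occurrences exist, a configurable degenerate value (default 0) is emitted
so feature rows stay complete — C is strictly positive whenever defined,
so the default is distinguishable from real values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError
from .sequence import SSSequence

#: Sentinel for "no truncation": sum over all observed distances (C_F).
FULL = None

#: Element order used for position-based feature columns.
PBF_ELEMENT_ORDER = ("C", "H", "E")


@dataclass(frozen=True)
class PBFParams:
    """Truncation bound and degeneracy handling for the C_k feature.

    ``k=None`` means no truncation (the C_F feature).  ``variance_ratio``
    selects the literal mean/variance ratio Semi-E/Semi-D instead of the
    reciprocal coefficient of variation Semi-E/sqrt(Semi-D); it exists for
    comparison only and is off by default.
    """

    k: int | None = FULL
    degenerate_value: float = 0.0
    variance_ratio: bool = False

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ConfigError(f"truncation bound k must be >= 1, got {self.k}")

    @property
    def label(self) -> str:
        """Short tag used in feature-column names ("F" for untruncated)."""
        return "F" if self.k is None else str(self.k)


def positions(s: SSSequence, element: str) -> tuple[int, ...]:
    """Ascending 1-based positions of ``element`` in the sequence."""
    return tuple(i for i, ch in enumerate(s.seq, start=1) if ch == element)


def interval_distances(po: tuple[int, ...]) -> tuple[int, ...]:
    """Successive differences of a position sequence.

    Empty when fewer than two positions exist; entries are >= 1 and sum to
    the span last(Po) - first(Po).
    """
    return tuple(b - a for a, b in zip(po, po[1:]))


def distance_distribution(nd: tuple[int, ...]) -> dict[int, float]:
    """Relative frequency of each distinct interval distance.

    An empty distance sequence yields an empty distribution (consumed by
    :func:`c_k` as a degenerate case).
    """
    if not nd:
        return {}
    counts: dict[int, int] = {}
    for d in nd:
        counts[d] = counts.get(d, 0) + 1
    total = len(nd)
    return {d: c / total for d, c in sorted(counts.items())}


def semi_mean(dist: dict[int, float], k: int | None = FULL) -> float:
    """Truncated first moment: sum of n P(n) over n <= k (all n if FULL)."""
    return sum(n * p for n, p in dist.items() if k is None or n <= k)


def semi_variance(dist: dict[int, float], k: int | None = FULL) -> float:
    """Truncated second central moment, probabilities not renormalized."""
    m1 = semi_mean(dist, k)
    m2 = sum(n * n * p for n, p in dist.items() if k is None or n <= k)
    return m2 - m1 * m1


def c_k(dist: dict[int, float], params: PBFParams = PBFParams()) -> float:
    """Reciprocal coefficient of variation of the truncated distribution.

    Returns ``params.degenerate_value`` when the distribution is empty or
    the truncated variance is not strictly positive.
    """
    if not dist:
        return params.degenerate_value
    var = semi_variance(dist, params.k)
    if var <= 0.0:
        return params.degenerate_value
    mean = semi_mean(dist, params.k)
    if params.variance_ratio:
        return mean / var
    return mean / math.sqrt(var)


def element_distribution(s: SSSequence, element: str) -> dict[int, float]:
    """Interval-distance distribution of one element of one sequence."""
    return distance_distribution(interval_distances(positions(s, element)))


def pbf_vector(
    s: SSSequence, params: PBFParams = PBFParams()
) -> dict[str, float]:
    """The 3-feature position-based row: C_k for elements C, H, E in order.

    Column names encode the truncation, e.g. ``CF_H`` or ``C5_H``.
    """
    return {
        f"C{params.label}_{e}": c_k(element_distribution(s, e), params)
        for e in PBF_ELEMENT_ORDER
    }
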