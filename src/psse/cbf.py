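"""Content-based features of predicted secondary-structure elements (CBF).

Nine widely used feature families computed from a 3-state sequence and its
segment decomposition:

* ``content``  — fraction of each element over the sequence.
* ``cmv``      — first/second-order composition moment vector: positions of
  an element summed (to the k-th power) and divided by (N-1)...(N-k).
* ``maxseg`` / ``nmaxseg`` — length of the longest segment of an element,
  raw and divided by N.
* ``avgseg`` / ``navgseg`` — mean segment length of an element, raw and
  divided by N.
* ``3pattern`` — for each interior residue, the (left, centre, right)
  window classified as eee / eex' / x'ee / x'ex' relative to the centre
  element e (x' = any different element); counts per (element, pattern),
  divided by the number of windows N-2.
* ``nalt``     — number of helix/strand alternations in the coil-free
  reduced segment sequence, divided by N.
* ``tpm``      — 2x2 transition probability matrix over adjacent pairs of
  the reduced segment sequence; a row with no outgoing pairs is all zero.

Conventions for absent elements: all segment statistics and the CMV return
0, so feature rows are always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, DegenerateInputError
from .segments import ALPHA, BETA, Segment, reduced_segment_sequence, segment_decompose
from .sequence import SSSequence

#: Feature families in canonical (column) order.
FAMILIES = (
    "content",
    "cmv",
    "maxseg",
    "nmaxseg",
    "avgseg",
    "navgseg",
    "3pattern",
    "nalt",
    "tpm",
)

#: Element order used for feature columns.
ELEMENT_ORDER = ("H", "E", "C")


def content(s: SSSequence) -> dict[str, float]:
    """Element content: count of each element divided by sequence length N.

    The three fractions sum to 1.
    """
    n = len(s)
    return {e: s.seq.count(e) / n for e in ELEMENT_ORDER}


def cmv(s: SSSequence, element: str, k: int) -> float:
    """Composition moment vector of order k (k in {1, 2}).

    Sum of the k-th powers of the 1-based occurrence positions of
    ``element``, divided by (N-1)·...·(N-k).  Returns 0 for an absent
    element.

    Raises
    ------
    DegenerateInputError
        If N <= k (the denominator would vanish or be negative).
    """
    if k not in (1, 2):
        raise ConfigError(f"CMV order must be 1 or 2, got {k}")
    n = len(s)
    if n <= k:
        raise DegenerateInputError(
            f"CMV order {k} undefined for sequence of length {n}"
        )
    denom = 1.0
    for d in range(1, k + 1):
        denom *= n - d
    total = sum(
        (i + 1) ** k for i, ch in enumerate(s.seq) if ch == element
    )
    return total / denom


def max_seg(segments: list[Segment], element: str) -> int:
    """Length of the longest segment of ``element`` (0 if none)."""
    lengths = [seg.length for seg in segments if seg.element == element]
    return max(lengths) if lengths else 0


def nmax_seg(segments: list[Segment], element: str, n: int) -> float:
    """Longest segment length divided by sequence length N."""
    return max_seg(segments, element) / n


def avg_seg(segments: list[Segment], element: str) -> float:
    """Mean length of the segments of ``element`` (0 if none)."""
    lengths = [seg.length for seg in segments if seg.element == element]
    return sum(lengths) / len(lengths) if lengths else 0.0


def navg_seg(segments: list[Segment], element: str, n: int) -> float:
    """Mean segment length divided by sequence length N."""
    return avg_seg(segments, element) / n


def three_pattern(
    s: SSSequence, normalize: bool = True
) -> dict[tuple[str, int], float]:
    """3-residue window patterns around every interior position.

    For each position i in [2, N-1] with centre element e, the window
    (s[i-1], e, s[i+1]) is one of four patterns: m=1 both neighbours equal
    e (eee), m=2 only the left (eex'), m=3 only the right (x'ee), m=4
    neither (x'ex').  Counts are divided by the number of windows N-2 when
    ``normalize`` (the default); the 12 fractions then sum to 1.  Sequences
    with N < 3 yield all zeros.
    """
    counts = {(e, m): 0 for e in ELEMENT_ORDER for m in (1, 2, 3, 4)}
    n = len(s)
    for i in range(1, n - 1):
        left, centre, right = s.seq[i - 1], s.seq[i], s.seq[i + 1]
        if left == centre and right == centre:
            m = 1
        elif left == centre:
            m = 2
        elif right == centre:
            m = 3
        else:
            m = 4
        counts[(centre, m)] += 1
    if not normalize or n < 3:
        return {key: float(c) for key, c in counts.items()}
    return {key: c / (n - 2) for key, c in counts.items()}


def _alternations(reduced: tuple[str, ...]) -> int:
    return sum(
        1 for a, b in zip(reduced, reduced[1:]) if a != b
    )


def nalt(s: SSSequence) -> float:
    """Normalized helix/strand alternation frequency.

    The number of adjacent state changes in the coil-free reduced segment
    sequence, divided by the sequence length N.  Higher for interspersed
    (alpha/beta) architectures than for segregated (alpha+beta) ones.
    """
    reduced = reduced_segment_sequence(segment_decompose(s))
    return _alternations(reduced) / len(s)


def tpm(s: SSSequence) -> dict[tuple[str, str], float]:
    """Transition probability matrix of the reduced segment sequence.

    Over adjacent pairs of the coil-free segment sequence,
    ``P[a][b] = count(a -> b) / count(a -> anything)``; a row whose
    denominator is 0 is emitted as all zeros.  Keys are state pairs over
    {"a", "b"} (helix, strand segments).
    """
    reduced = reduced_segment_sequence(segment_decompose(s))
    states = (ALPHA, BETA)
    counts = {(a, b): 0 for a in states for b in states}
    for a, b in zip(reduced, reduced[1:]):
        counts[(a, b)] += 1
    out: dict[tuple[str, str], float] = {}
    for a in states:
        row_total = sum(counts[(a, b)] for b in states)
        for b in states:
            out[(a, b)] = counts[(a, b)] / row_total if row_total else 0.0
    return out


@dataclass(frozen=True)
class CBFRecipe:
    """Which content-based feature families to emit, and for which elements.

    ``cmv_orders`` is restricted to {1, 2}; ``p3_normalize=False`` restores
    raw 3-pattern window counts instead of fractions.
    """

    families: tuple[str, ...] = FAMILIES
    elements: tuple[str, ...] = ELEMENT_ORDER
    cmv_orders: tuple[int, ...] = (1, 2)
    p3_normalize: bool = True

    def __post_init__(self) -> None:
        if not self.families:
            raise ConfigError("recipe selects no feature family")
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ConfigError(
                f"unknown feature families {unknown}; expected from {FAMILIES}"
            )
        if not set(self.elements) <= set(ELEMENT_ORDER):
            raise ConfigError(f"elements must be a subset of {ELEMENT_ORDER}")
        if not set(self.cmv_orders) <= {1, 2}:
            raise ConfigError("CMV orders must be a subset of {1, 2}")

    def column_names(self) -> list[str]:
        """Resolved column names in deterministic order."""
        elements = [e for e in ELEMENT_ORDER if e in self.elements]
        cols: list[str] = []
        for family in FAMILIES:
            if family not in self.families:
                continue
            if family == "content":
                cols += [f"content_{e}" for e in elements]
            elif family == "cmv":
                cols += [
                    f"cmv{k}_{e}"
                    for e in elements
                    for k in sorted(self.cmv_orders)
                ]
            elif family == "maxseg":
                cols += [f"maxseg_{e}" for e in elements]
            elif family == "nmaxseg":
                cols += [f"nmaxseg_{e}" for e in elements]
            elif family == "avgseg":
                cols += [f"avgseg_{e}" for e in elements]
            elif family == "navgseg":
                cols += [f"navgseg_{e}" for e in elements]
            elif family == "3pattern":
                cols += [
                    f"p3_{e}_m{m}" for e in elements for m in (1, 2, 3, 4)
                ]
            elif family == "nalt":
                cols.append("nalt")
            elif family == "tpm":
                cols += ["tpm_aa", "tpm_ab", "tpm_ba", "tpm_bb"]
        return cols


def cbf_vector(s: SSSequence, recipe: CBFRecipe = CBFRecipe()) -> dict[str, float]:
    """All content-based features of one sequence, as an ordered named row.

    Column order follows the family order above, elements H, E, C, CMV
    order 1 then 2, 3-pattern m ascending.
    """
    n = len(s)
    segs = segment_decompose(s)
    elements = [e for e in ELEMENT_ORDER if e in recipe.elements]
    row: dict[str, float] = {}
    for family in FAMILIES:
        if family not in recipe.families:
            continue
        if family == "content":
            cont = content(s)
            for e in elements:
                row[f"content_{e}"] = cont[e]
        elif family == "cmv":
            for e in elements:
                for k in sorted(recipe.cmv_orders):
                    row[f"cmv{k}_{e}"] = cmv(s, e, k)
        elif family == "maxseg":
            for e in elements:
                row[f"maxseg_{e}"] = float(max_seg(segs, e))
        elif family == "nmaxseg":
            for e in elements:
                row[f"nmaxseg_{e}"] = nmax_seg(segs, e, n)
        elif family == "avgseg":
            for e in elements:
                row[f"avgseg_{e}"] = avg_seg(segs, e)
        elif family == "navgseg":
            for e in elements:
                row[f"navgseg_{e}"] = navg_seg(segs, e, n)
        elif family == "3pattern":
            p3 = three_pattern(s, normalize=recipe.p3_normalize)
            for e in elements:
                for m in (1, 2, 3, 4):
                    row[f"p3_{e}_m{m}"] = p3[(e, m)]
        elif family == "nalt":
            row["nalt"] = nalt(s)
        elif family == "tpm":
            t = tpm(s)
            row["tpm_aa"] = t[(ALPHA, ALPHA)]
            row["tpm_ab"] = t[(ALPHA, BETA)]
            row["tpm_ba"] = t[(BETA, ALPHA)]
            row["tpm_bb"] = t[(BETA, BETA)]
    return row
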