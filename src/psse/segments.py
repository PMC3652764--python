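"""Maximal-run (segment) decomposition of secondary-structure sequences.

A segment is a maximal run of one element; e.g. CCHHHHEEEEECCCCCHHH
decomposes into (C,1,2) (H,3,4) (E,7,5) (C,12,5) (H,17,3).  Coordinates are
1-based and inclusive.  The reduced segment sequence keeps only the order of
helix and strand segments (states "a" and "b"), dropping coil segments —
the substrate for the alternation frequency and the transition probability
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .sequence import SSSequence

#: Reduced-segment states: "a" for a helix segment, "b" for a strand segment.
ALPHA, BETA = "a", "b"


@dataclass(frozen=True)
class Segment:
    element: str   # one of H, E, C
    start: int     # 1-based position of the first symbol
    length: int    # run length, >= 1

    @property
    def end(self) -> int:
        """1-based inclusive position of the last symbol."""
        return self.start + self.length - 1


def segment_decompose(s: SSSequence) -> list[Segment]:
    """Decompose a sequence into its ordered maximal segments.

    The segments are contiguous, cover positions 1..N, and adjacent
    segments carry different elements; expanding them reconstructs the
    sequence exactly.
    """
    out: list[Segment] = []
    pos = 1
    for element, run in groupby(s.seq):
        n = sum(1 for _ in run)
        out.append(Segment(element=element, start=pos, length=n))
        pos += n
    return out


def expand(segments: list[Segment]) -> str:
    """Inverse of :func:`segment_decompose`."""
    return "".join(seg.element * seg.length for seg in segments)


def reduced_segment_sequence(segments: list[Segment]) -> tuple[str, ...]:
    """Map H-segments to "a", E-segments to "b", and drop coil segments.

    Order is preserved; removing coils can juxtapose two segments of the
    same state, so consecutive equal entries are retained.  All-coil input
    yields an empty tuple.
    """
    mapping = {"H": ALPHA, "E": BETA}
    return tuple(
        mapping[seg.element] for seg in segments if seg.element != "C"
    )
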