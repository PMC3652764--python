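"""Class-typed synthetic secondary-structure sequence generator.

Generates H/E/C strings segment by segment: a Markov chain over segment
TYPES (never repeating the previous type, so maximal runs are genuine)
with geometric segment LENGTHS (memoryless, one mean per type, minimum 1),
until a target sequence length drawn uniformly per sequence is reached.
Segment-level generation is used because every feature in this package is
a function of segments and gaps, which gives direct control over the
statistics under test.

The four class presets caricature the architectures of the SCOP classes:

* all-alpha   — helix/coil alternation, long helices, no strand;
* all-beta    — strand/coil alternation, no helix;
* alpha/beta  — interleaved helices and strands with short coils
  (high helix/strand alternation);
* alpha+beta  — a helix/coil block followed by a strand/coil block
  (segregated, hence low alternation).

The preset parameters are arbitrary but realistic defaults (segment means
of a few residues, chain lengths 100-300), not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .sequence import CLASSES, LabeledDataset, SSSequence

_ID_SLUGS = {
    "all-alpha": "a",
    "all-beta": "b",
    "alpha/beta": "ab",
    "alpha+beta": "apb",
}


@dataclass(frozen=True)
class Phase:
    """One stretch of the chain: type-transition weights + start weights."""

    transitions: dict[str, dict[str, float]]
    start: dict[str, float]
    fraction: float = 1.0

    def __post_init__(self) -> None:
        for state, row in self.transitions.items():
            if state in row and row[state] > 0:
                raise ConfigError(
                    f"self-transition {state}->{state} would merge segments"
                )
            if any(w < 0 for w in row.values()) or sum(row.values()) <= 0:
                raise ConfigError(f"invalid transition weights from {state!r}")
        if sum(self.start.values()) <= 0:
            raise ConfigError("start weights must sum > 0")
        if not 0 < self.fraction <= 1:
            raise ConfigError("phase fraction must be in (0, 1]")


@dataclass(frozen=True)
class ClassPreset:
    """Generator settings for one structural class."""

    label: str
    phases: tuple[Phase, ...]
    mean_len: dict[str, float]
    length_range: tuple[int, int] = (100, 300)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ConfigError("preset needs at least one phase")
        if abs(sum(p.fraction for p in self.phases) - 1.0) > 1e-9:
            raise ConfigError("phase fractions must sum to 1")
        if any(m < 1 for m in self.mean_len.values()):
            raise ConfigError("mean segment lengths must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid length range {self.length_range}")


def default_presets() -> dict[str, ClassPreset]:
    """The four built-in class presets (see module docstring)."""
    hc = Phase(
        transitions={"H": {"C": 1.0}, "C": {"H": 1.0}},
        start={"C": 1.0, "H": 1.0},
    )
    ec = Phase(
        transitions={"E": {"C": 1.0}, "C": {"E": 1.0}},
        start={"C": 1.0, "E": 1.0},
    )
    interleaved = Phase(
        transitions={
            "H": {"C": 0.7, "E": 0.3},
            "E": {"C": 0.7, "H": 0.3},
            "C": {"H": 0.5, "E": 0.5},
        },
        start={"C": 1.0, "H": 1.0, "E": 1.0},
    )
    return {
        "all-alpha": ClassPreset(
            label="all-alpha",
            phases=(hc,),
            mean_len={"H": 9.0, "C": 5.0},
        ),
        "all-beta": ClassPreset(
            label="all-beta",
            phases=(ec,),
            mean_len={"E": 5.0, "C": 5.0},
        ),
        "alpha/beta": ClassPreset(
            label="alpha/beta",
            phases=(interleaved,),
            mean_len={"H": 8.0, "E": 5.0, "C": 3.0},
        ),
        "alpha+beta": ClassPreset(
            label="alpha+beta",
            phases=(
                Phase(transitions=hc.transitions, start=hc.start, fraction=0.5),
                Phase(transitions=ec.transitions, start=ec.start, fraction=0.5),
            ),
            mean_len={"H": 9.0, "E": 5.0, "C": 5.0},
        ),
    }


def _weighted_choice(
    rng: np.random.Generator, weights: dict[str, float], exclude: str | None
) -> str:
    items = [
        (s, w) for s, w in sorted(weights.items()) if w > 0 and s != exclude
    ]
    if not items:
        raise ConfigError(
            f"no segment type available after excluding {exclude!r}"
        )
    states, ws = zip(*items)
    p = np.asarray(ws, dtype=float)
    return states[rng.choice(len(states), p=p / p.sum())]


def generate_sequence(
    preset: ClassPreset, rng: np.random.Generator, id: str = "synthetic"
) -> SSSequence:
    """Emit one sequence from a class preset.

    A target length is drawn uniformly from ``preset.length_range``; each
    phase contributes its fraction of that target, and the final segment of
    each phase is truncated at the phase boundary.  Consecutive segment
    types always differ, also across phase boundaries.
    """
    lo, hi = preset.length_range
    target = int(rng.integers(lo, hi + 1))
    chunks: list[str] = []
    emitted = 0
    prev: str | None = None
    for pi, phase in enumerate(preset.phases):
        budget = (
            target - emitted
            if pi == len(preset.phases) - 1
            else round(phase.fraction * target)
        )
        phase_emitted = 0
        state: str | None = None
        while phase_emitted < budget:
            if state is None:
                state = _weighted_choice(rng, phase.start, exclude=prev)
            else:
                state = _weighted_choice(
                    rng, phase.transitions[state], exclude=None
                )
            mean = preset.mean_len.get(state, 1.0)
            length = int(rng.geometric(1.0 / mean)) if mean > 1 else 1
            length = min(length, budget - phase_emitted)
            chunks.append(state * length)
            phase_emitted += length
            prev = state
        emitted += phase_emitted
    return SSSequence(id=id, seq="".join(chunks))


@dataclass
class SyntheticDataset:
    """A labeled dataset plus the presets and seed that produced it."""

    dataset: LabeledDataset
    seed: int
    presets: dict[str, ClassPreset] = field(repr=False, default_factory=dict)


def generate_dataset(
    n_per_class: int,
    presets: dict[str, ClassPreset] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a balanced labeled dataset, bit-reproducible from the seed.

    Sequence i of class index c uses its own generator seeded by
    ``SeedSequence(seed, spawn_key=(c, i))``, so any subset regenerates
    identically regardless of generation order.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    if presets is None:
        presets = default_presets()
    sequences: list[SSSequence] = []
    labels: dict[str, str] = {}
    ordered = [c for c in CLASSES if c in presets] + sorted(
        set(presets) - set(CLASSES)
    )
    for ci, cls in enumerate(ordered):
        slug = _ID_SLUGS.get(cls, f"c{ci}")
        for i in range(n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
            )
            sid = f"{slug}{i:04d}"
            sequences.append(generate_sequence(presets[cls], rng, id=sid))
            labels[sid] = cls
    return SyntheticDataset(
        dataset=LabeledDataset(sequences=sequences, labels=labels),
        seed=seed,
        presets=dict(presets),
    )
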