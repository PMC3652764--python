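"""Core domain types: 3-state secondary-structure sequences and labeled datasets.

A predicted secondary structure assigns every residue one of three states:
H (alpha-helix), E (beta-strand) or C (coil).  All feature extraction in this
package operates on such strings; positions are 1-based throughout, so the
first residue of a sequence has position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlphabetError, ConfigError

#: The 3-state secondary-structure alphabet (PSIPRED-style).
ALPHABET = ("H", "E", "C")
_ALPHABET_SET = frozenset(ALPHABET)

#: Canonical SCOP-style structural-class labels, in reporting order.
CLASSES = ("all-alpha", "all-beta", "alpha/beta", "alpha+beta")

#: Accepted spellings for each class (matched case-insensitively).
CLASS_ALIASES = {
    "all-alpha": "all-alpha",
    "all-a": "all-alpha",
    "all-α": "all-alpha",
    "alpha": "all-alpha",
    "a": "all-alpha",
    "all-beta": "all-beta",
    "all-b": "all-beta",
    "all-β": "all-beta",
    "beta": "all-beta",
    "b": "all-beta",
    "alpha/beta": "alpha/beta",
    "a/b": "alpha/beta",
    "α/β": "alpha/beta",
    "alpha+beta": "alpha+beta",
    "a+b": "alpha+beta",
    "α+β": "alpha+beta",
}


def normalize_class(name: str) -> str:
    """Map a class-label spelling onto its canonical form.

    Raises
    ------
    ConfigError
        If ``name`` is not a recognized alias of one of the four classes.
    """
    key = name.strip().lower()
    try:
        return CLASS_ALIASES[key]
    except KeyError:
        raise ConfigError(
            f"unknown structural class {name!r}; expected one of "
            f"{sorted(set(CLASS_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class SSSequence:
    """An identified string over the alphabet {H, E, C}.

    Parameters
    ----------
    id : str
        Sequence identifier (e.g. a PDB code).
    seq : str
        The secondary-structure string; validated and upper-cased on
        construction.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0:
            raise AlphabetError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(self.seq, start=1):
            if ch not in _ALPHABET_SET:
                raise AlphabetError(
                    f"sequence {self.id!r}: symbol {ch!r} at position {i} "
                    "is not in {H, E, C}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """A list of sequences with exactly one structural-class label each."""

    sequences: list[SSSequence]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigError(f"duplicate sequence ids: {dup}")
        self.labels = {i: normalize_class(c) for i, c in self.labels.items()}
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ConfigError(f"sequences without a class label: {missing}")
        orphans = sorted(set(self.labels) - set(ids))
        if orphans:
            raise ConfigError(f"labels without a sequence: {orphans}")

    def __len__(self) -> int:
        return len(self.sequences)

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.sequences:
            c = self.labels[s.id]
            sizes[c] = sizes.get(c, 0) + 1
        return sizes
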