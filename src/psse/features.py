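"""The FeatureMatrix container: named feature columns × sequence rows."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError


@dataclass
class FeatureMatrix:
    """A rectangular, fully populated table of real-valued features.

    ``values`` is indexed by sequence id with one named feature per column;
    ``recipe`` records the feature-set specification that produced it
    (family selection, PBF truncation k, scaling), so a table on disk is
    self-describing.
    """

    values: pd.DataFrame
    recipe: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise FormatError("feature matrix contains missing values")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return self.values.equals(other.values)
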