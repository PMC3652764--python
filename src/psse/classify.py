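"""Feature-set assembly, RBF-SVM structural-class prediction, jackknife.

The classification protocol: assemble a named feature set per sequence,
standardize the columns, pick the SVM hyperparameters (C, gamma) once by
grid search over powers of two with 10-fold cross-validation, then score
by the jackknife (leave-one-out) test — per-class accuracy TP_j/|C_j| and
overall accuracy sum(TP_j)/sum(|C_j|).

Selecting (C, gamma) on the same data the jackknife scores is mildly
optimistic; pass ``nested=True`` to re-run the grid search inside every
jackknife fold for an honest (and far slower) estimate.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .cbf import CBFRecipe, FAMILIES, cbf_vector
from .errors import ConfigError
from .features import FeatureMatrix
from .pbf import PBFParams, pbf_vector
from .sequence import CLASSES, LabeledDataset

#: Default composition of the 11-dimension content-based block used in the
#: combined "pbf11cbf" feature set.  The choice spans the widely used
#: families (content, longest/average segment lengths, alternation, CMV);
#: it is a documented default, overridable via ``FeatureSetSpec``.
PBF11CBF_COLUMNS = (
    "content_H",
    "content_E",
    "content_C",
    "maxseg_H",
    "maxseg_E",
    "nmaxseg_H",
    "nmaxseg_E",
    "avgseg_H",
    "avgseg_E",
    "nalt",
    "cmv1_H",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named recipe: a content-based block and/or the position-based block.

    ``cbf_columns`` optionally restricts the content-based block to an
    explicit column subset (used by the combined 14-feature preset).
    """

    name: str = "custom"
    cbf: CBFRecipe | None = None
    pbf: PBFParams | None = None
    cbf_columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.cbf is None and self.pbf is None:
            raise ConfigError(f"feature set {self.name!r} selects nothing")
        if self.cbf_columns is not None:
            if self.cbf is None:
                raise ConfigError("cbf_columns given without a CBF recipe")
            available = set(self.cbf.column_names())
            missing = [c for c in self.cbf_columns if c not in available]
            if missing:
                raise ConfigError(
                    f"cbf_columns not produced by the recipe: {missing}"
                )

    def column_names(self) -> list[str]:
        """Resolved feature columns, deterministic order (CBF then PBF)."""
        cols: list[str] = []
        if self.cbf is not None:
            if self.cbf_columns is not None:
                cols += list(self.cbf_columns)
            else:
                cols += self.cbf.column_names()
        if self.pbf is not None:
            cols += [f"C{self.pbf.label}_{e}" for e in ("C", "H", "E")]
        return cols

    def describe(self) -> dict:
        """JSON-serializable recipe record."""
        out: dict = {"name": self.name}
        if self.cbf is not None:
            out["cbf_families"] = list(self.cbf.families)
            if self.cbf_columns is not None:
                out["cbf_columns"] = list(self.cbf_columns)
        if self.pbf is not None:
            out["pbf_k"] = "full" if self.pbf.k is None else self.pbf.k
        return out


def feature_set(name: str, pbf_k: int | None = None) -> FeatureSetSpec:
    """Resolve a preset name into a :class:`FeatureSetSpec`.

    Presets: each single content-based family (``content`` ... ``tpm``),
    ``pbf`` (the 3-feature position-based set), ``<family>+CF`` combined
    sets, ``cbf`` (all nine families), and ``pbf11cbf`` (the 14-feature
    combined set: an 11-column content-based block plus the 3 position
    features).  ``pbf_k`` sets the truncation for the position block
    (default: no truncation, i.e. C_F).
    """
    key = name.strip().lower()
    pbf_params = PBFParams(k=pbf_k)
    if key in ("pbf", "cf"):
        return FeatureSetSpec(name=key, pbf=pbf_params)
    if key == "cbf":
        return FeatureSetSpec(name=key, cbf=CBFRecipe())
    if key == "pbf11cbf":
        return FeatureSetSpec(
            name=key,
            cbf=CBFRecipe(),
            cbf_columns=PBF11CBF_COLUMNS,
            pbf=pbf_params,
        )
    combined = key.endswith("+cf")
    family = key[:-3] if combined else key
    if family in FAMILIES:
        return FeatureSetSpec(
            name=key,
            cbf=CBFRecipe(families=(family,)),
            pbf=pbf_params if combined else None,
        )
    raise ConfigError(f"unknown feature-set preset {name!r}")


def feature_rows(sequences, spec: FeatureSetSpec) -> FeatureMatrix:
    """Raw (unscaled) feature rows for a list of sequences."""
    sequences = list(sequences)
    if not sequences:
        raise ConfigError("cannot assemble features for an empty dataset")
    rows = []
    for s in sequences:
        row: dict[str, float] = {}
        if spec.cbf is not None:
            row.update(cbf_vector(s, spec.cbf))
        if spec.pbf is not None:
            row.update(pbf_vector(s, spec.pbf))
        rows.append(row)
    df = pd.DataFrame(rows, index=[s.id for s in sequences])
    df = df[spec.column_names()]
    return FeatureMatrix(values=df, recipe=spec.describe())


def assemble_features(
    ds: LabeledDataset, spec: FeatureSetSpec, scale: bool = True
) -> FeatureMatrix:
    """One feature row per sequence, columns per the feature-set spec.

    With ``scale`` (the default) every column is standardized to zero mean
    and unit variance over the dataset (constant columns become all-zero);
    the scaling is recorded in the recipe.  Heterogeneous unscaled features
    would let raw segment lengths dominate the RBF kernel.
    """
    df = feature_rows(ds.sequences, spec).values
    if scale:
        mean = df.mean(axis=0)
        std = df.std(axis=0, ddof=0)
        std[std == 0.0] = 1.0
        df = (df - mean) / std
    recipe = spec.describe() | {"scaled": bool(scale)}
    return FeatureMatrix(values=df, recipe=recipe)


#: Power-of-two grid 2^-5 .. 2^5 for both C and gamma.
DEFAULT_GRID = tuple(2.0 ** e for e in range(-5, 6))


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameter grids and cross-validation settings."""

    c_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ConfigError("hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise ConfigError("cross-validation needs at least 2 folds")


def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ConfigError("need at least 2 classes to fit a classifier")


def grid_search(
    fm: FeatureMatrix, labels: dict[str, str], cfg: SVMConfig = SVMConfig()
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing mean k-fold overall accuracy.

    Folds are stratified and shuffled with ``cfg.seed``; if the smallest
    class has fewer members than ``cfg.folds`` the fold count is reduced
    (with a warning).

    The CV score surface typically plateaus over a wide (C, gamma) region,
    so exact ties are common.  Ties are broken toward the middle of the
    plateau: the tied candidates are sorted by (C, gamma) and the median
    one is returned.  The low-C edge of a plateau is a barely fitted
    classifier whose tiny functional margins can tie in class-balanced CV
    yet collapse under the leave-one-out test (whose training splits are
    never balanced); the high-C/high-gamma edge borders overfitting.  The
    plateau centre is maximally far from both failure modes.
    """
    X = fm.values.to_numpy()
    y = np.asarray([labels[i] for i in fm.ids])
    _check_labels(y)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    folds = cfg.folds
    if min_class < folds:
        folds = max(2, min_class)
        _warnings.warn(
            f"smallest class has {min_class} members; reducing CV folds "
            f"from {cfg.folds} to {folds}",
            stacklevel=2,
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(cv.split(X, y))
    scores: dict[tuple[float, float], float] = {}
    for c in sorted(cfg.c_grid):
        for gamma in sorted(cfg.gamma_grid):
            clf = SVC(kernel="rbf", C=c, gamma=gamma)
            scores[(c, gamma)] = cross_val_score(clf, X, y, cv=splits).mean()
    best_score = max(scores.values())
    tied = sorted(
        pair for pair, s in scores.items() if s >= best_score - 1e-12
    )
    return tied[len(tied) // 2]


@dataclass
class EvaluationReport:
    """Jackknife confusion counts and the accuracies derived from them."""

    confusion: pd.DataFrame          # rows = true class, cols = predicted
    per_class: dict[str, float]      # Accuracy_j = TP_j / |C_j|
    overall: float                   # sum TP_j / sum |C_j|
    c: float
    gamma: float
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.confusion.sum(axis=1)
        weighted = sum(
            self.per_class[c] * sizes[c] for c in self.confusion.index
        ) / sizes.sum()
        if abs(weighted - self.overall) > 1e-12:
            raise ValueError(
                "overall accuracy must equal the class-size-weighted mean "
                "of per-class accuracies"
            )

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "overall": self.overall,
            "confusion": {
                t: self.confusion.loc[t].to_dict() for t in self.confusion.index
            },
            "C": self.c,
            "gamma": self.gamma,
            "warnings": self.warnings,
        }


def jackknife_evaluate(
    fm: FeatureMatrix,
    labels: dict[str, str],
    cfg: SVMConfig = SVMConfig(),
    chosen: tuple[float, float] | None = None,
    nested: bool = False,
) -> EvaluationReport:
    """Leave-one-out evaluation of the RBF-SVM on a feature matrix.

    Each sequence is predicted by a model trained on the remaining n-1.
    ``chosen`` fixes (C, gamma) for every fold (run :func:`grid_search`
    first); with ``nested=True`` the grid search is instead repeated inside
    every fold, which removes selection optimism at ~n times the cost.
    """
    X = fm.values.to_numpy()
    y = np.asarray([labels[i] for i in fm.ids])
    _check_labels(y)
    if not nested and chosen is None:
        chosen = grid_search(fm, labels, cfg)
    classes = [c for c in CLASSES if c in set(y)] + sorted(
        set(y) - set(CLASSES)
    )
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    warn_msgs: list[str] = []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if y[i] not in set(y[mask]):
            warn_msgs.append(
                f"{fm.ids[i]}: its class {y[i]!r} has a single member, "
                "absent from the training split"
            )
        if nested:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                sub = FeatureMatrix(
                    values=fm.values.iloc[mask], recipe=fm.recipe
                )
                c, gamma = grid_search(sub, labels, cfg)
        else:
            c, gamma = chosen  # type: ignore[misc]
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
        clf.fit(X[mask], y[mask])
        pred = clf.predict(X[i : i + 1])[0]
        confusion.loc[y[i], pred] += 1
    sizes = confusion.sum(axis=1)
    per_class = {
        c: confusion.loc[c, c] / sizes[c] for c in classes
    }
    overall = float(np.trace(confusion.to_numpy()) / sizes.sum())
    if nested:
        c, gamma = float("nan"), float("nan")
    else:
        c, gamma = chosen  # type: ignore[misc]
    return EvaluationReport(
        confusion=confusion,
        per_class={k: float(v) for k, v in per_class.items()},
        overall=overall,
        c=float(c),
        gamma=float(gamma),
        warnings=warn_msgs,
    )


def accuracy_report(report: EvaluationReport) -> str:
    """Format per-class and overall accuracies as a percentage table."""
    classes = list(report.confusion.index)
    header = "Class       Accuracy (%)"
    lines = [header, "-" * len(header)]
    for c in classes:
        lines.append(f"{c:<12}{100 * report.per_class[c]:>10.2f}")
    lines.append(f"{'Overall':<12}{100 * report.overall:>10.2f}")
    lines.append("")
    lines.append("Confusion (rows = true, columns = predicted):")
    lines.append(report.confusion.to_string())
    return "\n".join(lines)
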