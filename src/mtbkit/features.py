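"""Non-expression module features and the anti-correlation class predictor.

Seven features describe a module using the network alone: its side sizes,
the interaction density inside the defining submatrix, the densities of the
three out-of-module regions sharing its rows or columns, and the module
type.  The prediction target is the module's within-module miRNA-mRNA
anti-correlation summarised into ten equal-width classes; a cross-validated
multi-class classifier (default: random forest) then measures how well the
network-only features identify modules with strong expression
anti-correlation, reported as the mean one-vs-rest AUC.  An exhaustive
search over all feature subsets ranks which features carry the signal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import MTB, MTB_TYPES
from .evalstats import _mtb_pair_values, fraction_beyond
from .netio import ExpressionMatrix, InteractionNetwork

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_features",
    "bin_equal_width",
    "anticorrelation_classes",
    "crossval_auc",
    "exhaustive_feature_search",
    "feature_matrix",
]

FEATURE_NAMES = ("n_mrnas", "n_mirnas", "density_in", "density_rows_out",
                 "density_cols_out", "density_either_out", "mtb_type")


@dataclass(frozen=True)
class FeatureVector:
    """The seven network-only features of one module."""

    n_mrnas: int
    n_mirnas: int
    density_in: float
    density_rows_out: float    # other rows of the defining columns
    density_cols_out: float    # other columns of the defining rows
    density_either_out: float  # both outside regions pooled
    type_code: str

    def __post_init__(self) -> None:
        if self.n_mrnas < 1 or self.n_mirnas < 1:
            raise ValueError("side sizes must be >= 1")
        for v in (self.density_in, self.density_rows_out,
                  self.density_cols_out, self.density_either_out):
            if not (0.0 <= v <= 1.0):
                raise ValueError("densities must lie in [0, 1]")
        if self.type_code not in MTB_TYPES:
            raise ValueError(f"unknown type code {self.type_code!r}")

    def to_array(self) -> np.ndarray:
        return np.array([
            float(self.n_mrnas), float(self.n_mirnas), self.density_in,
            self.density_rows_out, self.density_cols_out,
            self.density_either_out, float(MTB_TYPES.index(self.type_code))])


def compute_features(mtb: MTB, network: InteractionNetwork) -> FeatureVector:
    """Exact region densities of a module within its network.

    Empty outside regions (whole-matrix modules) contribute density 0 by
    convention.
    """
    rows = sorted(mtb.rows)
    cols = sorted(mtb.cols)
    if rows[-1] >= network.n_mrnas or cols[-1] >= network.n_mirnas \
            or rows[0] < 0 or cols[0] < 0:
        raise IndexError("module indices outside the network")
    adj = network.adjacency
    other_rows = sorted(set(range(network.n_mrnas)) - mtb.rows)
    other_cols = sorted(set(range(network.n_mirnas)) - mtb.cols)

    def region_density(r: list, c: list) -> tuple[int, int]:
        if not r or not c:
            return 0, 0
        sub = adj[np.ix_(r, c)]
        return int(sub.sum()), sub.size

    ones_in, cells_in = region_density(rows, cols)
    ones_ro, cells_ro = region_density(other_rows, cols)
    ones_co, cells_co = region_density(rows, other_cols)
    return FeatureVector(
        n_mrnas=len(rows),
        n_mirnas=len(cols),
        density_in=ones_in / cells_in,
        density_rows_out=ones_ro / cells_ro if cells_ro else 0.0,
        density_cols_out=ones_co / cells_co if cells_co else 0.0,
        density_either_out=((ones_ro + ones_co) / (cells_ro + cells_co)
                            if cells_ro + cells_co else 0.0),
        type_code=mtb.mtb_type,
    )


def feature_matrix(mtbs: Sequence[MTB],
                   network: InteractionNetwork) -> np.ndarray:
    """Stacked feature arrays, one row per module (type as a numeric code)."""
    return np.vstack([compute_features(b, network).to_array() for b in mtbs])


def bin_equal_width(fractions, n_classes: int = 10) -> np.ndarray:
    """Equal-width class labels on [0, 1]; the last class is closed at 1."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    fractions = np.asarray(fractions, dtype=float)
    if np.isnan(fractions).any() or (fractions < 0).any() \
            or (fractions > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    return np.minimum((fractions * n_classes).astype(int), n_classes - 1)


def anticorrelation_classes(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    t: float = -0.1,
    n_classes: int = 10,
    variant: Literal["fraction", "mean"] = "fraction",
) -> np.ndarray:
    """Ten-class anti-correlation target for the feature classifier.

    The default class variable is the fraction of within-module miRNA-mRNA
    correlations more negative than t, cut into equal-width classes.  The
    ``mean`` variant instead bins the average anti-correlation, mapped onto
    [0, 1] as (1 - mean r) / 2.
    """
    values = [_mtb_pair_values(b, network, expr_mirna, expr_mrna,
                               "mirna_mrna") for b in mtbs]
    if variant == "fraction":
        stat = [fraction_beyond(v, t, "below") for v in values]
    elif variant == "mean":
        stat = [(1.0 - float(np.nanmean(v))) / 2.0 if np.any(~np.isnan(v))
                else float("nan") for v in values]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    stat = np.nan_to_num(np.asarray(stat, dtype=float), nan=0.0)
    return bin_equal_width(np.clip(stat, 0.0, 1.0), n_classes)


def _default_classifier(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def crossval_auc(
    features: np.ndarray,
    classes: Sequence[int],
    n_folds: int = 10,
    classifier_factory=None,
    seed: int = 0,
) -> float:
    """Mean one-vs-rest AUC over stratified cross-validation folds.

    Per fold, a fresh classifier is fitted on the training split; for every
    class present in the test split with both positive and negative
    examples, the one-vs-rest AUC of its predicted probability is computed;
    class AUCs are averaged within the fold and fold means are averaged.
    Folds are reduced (with a warning) when the rarest class has fewer
    members than requested folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(classes)
    if X.ndim == 1:
        X = X[:, None]
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < n_folds:
        warnings.warn(f"rarest class has {counts.min()} members; "
                      f"folds reduced from {n_folds}", stacklevel=2)
        n_folds = max(2, int(counts.min()))
    if classifier_factory is None:
        classifier_factory = _default_classifier
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train, test in skf.split(X, y):
        clf = classifier_factory(seed)
        clf.fit(X[train], y[train])
        proba = np.asarray(clf.predict_proba(X[test]))
        clf_labels = list(clf.classes_)
        class_aucs = []
        for label in labels:
            mask = y[test] == label
            if label not in clf_labels or mask.all() or not mask.any():
                continue
            class_aucs.append(
                roc_auc_score(mask, proba[:, clf_labels.index(label)]))
        if class_aucs:
            fold_aucs.append(float(np.mean(class_aucs)))
    if not fold_aucs:
        raise ValueError("no fold produced a defined AUC")
    return float(np.mean(fold_aucs))


@dataclass
class FeatureSearchReport:
    """Exhaustively ranked feature subsets and inclusion frequencies."""

    ranked: list  # (subset of feature names, mean AUC), best first
    inclusion_frequency: dict  # feature name -> share among top subsets
    n_subsets: int


def exhaustive_feature_search(
    features: np.ndarray,
    classes: Sequence[int],
    n_folds: int = 10,
    classifier_factory=None,
    seed: int = 0,
    n_top: int = 10,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> FeatureSearchReport:
    """Cross-validated AUC of every non-empty feature subset.

    With the seven standard features this evaluates 2^7 - 1 = 127 subsets.
    Subsets are ranked by mean AUC (ties broken by smaller subsets first,
    then name order); inclusion frequencies are computed over the *n_top*
    best subsets.
    """
    X = np.asarray(features, dtype=float)
    n_feat = X.shape[1]
    if len(feature_names) != n_feat:
        raise ValueError("feature_names length must match feature columns")
    results = []
    for size in range(1, n_feat + 1):
        for subset in itertools.combinations(range(n_feat), size):
            auc = crossval_auc(X[:, subset], classes, n_folds,
                               classifier_factory, seed)
            results.append((tuple(feature_names[i] for i in subset), auc))
    results.sort(key=lambda r: (-r[1], len(r[0]), r[0]))
    top = results[:n_top]
    freq = {name: sum(name in subset for subset, _ in top) / len(top)
            for name in feature_names}
    return FeatureSearchReport(results, freq, len(results))
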