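"""Feature tables, decision-tree induction and stratified cross-validation.

Three abstract representations of a voltammogram are supported:

* ``minima3``   — potential and current of the three catalytic minima
  RS2Co, Cat1 and Cat2 (6 features; blood and muscle are excluded because
  their curves do not resolve six significant extremes);
* ``extremes6`` — potential and current of all six extremes, in
  acquisition order (12 features; same exclusion);
* ``wavelet32`` — the 32 level-5 Haar step attributes (all nine tissues).

Trees are induced greedily on information gain with a minimal-leaf-size
constraint (default 10 rows, about two rats' worth of replicates) and
evaluated by stratified 10-fold cross-validation with a pooled confusion
matrix whose rows are the predicted class and columns the true class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, export_text

from .errors import ParameterError
from .extremes import (DEFAULT_MIN_DISTANCE, find_extremes,
                       merge_close_extremes, name_peaks)
from .io import Dataset
from .wavelet import wavelet_attributes

log = logging.getLogger(__name__)

MODES = ("minima3", "extremes6", "wavelet32")
SIX_EXTREME_EXCLUDED = ("blood", "muscle")
DEFAULT_MINIMAL_LEAF_SIZE = 10

_META = ["tissue", "subject", "replicate"]


@dataclass
class FeatureTable:
    """One row per curve: feature columns plus tissue / subject labels."""

    frame: pd.DataFrame
    mode: str

    @property
    def features(self) -> pd.DataFrame:
        return self.frame.drop(columns=_META)

    @property
    def labels(self) -> pd.Series:
        return self.frame["tissue"]

    def __len__(self) -> int:
        return len(self.frame)


def build_feature_table(dataset: Dataset, mode: str,
                        min_distance: int = DEFAULT_MIN_DISTANCE,
                        windows=None, wavelet_level: int = 5) -> FeatureTable:
    """Construct the feature table for a cleaned dataset.

    Curves that lack a required named peak (or do not show exactly six
    merged extremes in ``extremes6`` mode) are excluded with a logged count.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    rows = []
    skipped = 0
    for curve in dataset:
        meta = dict(zip(_META, curve.key))
        if mode == "wavelet32":
            att = wavelet_attributes(curve, wavelet_level)
            rows.append({**meta, **dict(zip(att.names(), att.coefs))})
            continue
        if curve.tissue in SIX_EXTREME_EXCLUDED:
            continue
        ext = merge_close_extremes(find_extremes(curve), min_distance)
        if mode == "minima3":
            named = name_peaks(ext, windows)
            refs = [named.rs2co, named.cat1, named.cat2]
            if any(r is None for r in refs):
                skipped += 1
                continue
            row = dict(meta)
            for name, ref in zip(("rs2co", "cat1", "cat2"), refs):
                row[f"{name}_potential"] = ref.potential
                row[f"{name}_current"] = ref.value
            rows.append(row)
        else:  # extremes6
            if len(ext) != 6:
                skipped += 1
                continue
            row = dict(meta)
            for j in range(6):
                row[f"ext{j + 1}_potential"] = float(ext.potentials[j])
                row[f"ext{j + 1}_current"] = float(ext.values[j])
            rows.append(row)
    if skipped:
        log.info("build_feature_table(%s): excluded %d curves lacking "
                 "the required extremes", mode, skipped)
    frame = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureTable(frame, mode)


@dataclass
class DecisionTreeModel:
    """A fitted tree plus the feature-column contract it was trained on."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(features[self.feature_names].to_numpy())

    def render(self) -> str:
        return export_text(self.estimator, feature_names=self.feature_names)


def induce_tree(table: FeatureTable,
                minimal_leaf_size: int = DEFAULT_MINIMAL_LEAF_SIZE,
                random_state: int = 0) -> DecisionTreeModel:
    """Greedy information-gain tree with a minimal-leaf-size constraint."""
    if len(table) == 0:
        raise ParameterError("empty feature table")
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        # degenerate but legal: a single-leaf majority tree
        pass
    est = DecisionTreeClassifier(criterion="entropy",
                                 min_samples_leaf=minimal_leaf_size,
                                 random_state=random_state)
    est.fit(table.features.to_numpy(), y)
    return DecisionTreeModel(est, list(table.features.columns),
                             list(est.classes_))


@dataclass
class CVResult:
    """Pooled confusion matrix (rows = predicted, columns = true) plus
    fold-wise accuracies."""

    classes: list[str]
    confusion: np.ndarray
    fold_accuracies: np.ndarray

    @property
    def accuracy_mean(self) -> float:
        """Mean fold accuracy, percent."""
        return 100.0 * float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        """Sample standard deviation of the fold accuracies, percent."""
        return 100.0 * float(self.fold_accuracies.std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        idx = [f"pred. {c}" for c in self.classes]
        cols = [f"true {c}" for c in self.classes]
        return pd.DataFrame(self.confusion, index=idx, columns=cols)


def cross_validate(table: FeatureTable, folds: int = 10,
                   minimal_leaf_size: int = DEFAULT_MINIMAL_LEAF_SIZE,
                   seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation with a pooled confusion matrix."""
    y = table.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if len(small):
        raise ParameterError(
            f"class(es) {', '.join(small)} have fewer than {folds} members")
    x = table.features.to_numpy()
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    accs = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        est = DecisionTreeClassifier(criterion="entropy",
                                     min_samples_leaf=minimal_leaf_size,
                                     random_state=seed)
        est.fit(x[train], y[train])
        pred = est.predict(x[test])
        for p, t in zip(pred, y[test]):
            confusion[index[p], index[t]] += 1
        accs.append(float(np.mean(pred == y[test])))
    return CVResult(classes, confusion, np.asarray(accs))


def confusion_metrics(confusion: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class precision and recall (percent) and overall accuracy.

    Rows are predictions, columns truths: precision_c = M[c,c] / row-sum,
    recall_c = M[c,c] / column-sum; empty rows/columns yield NaN.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("confusion matrix must be square")
    if (m < 0).any():
        raise ParameterError("confusion matrix must be non-negative")
    diag = np.diag(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = 100.0 * diag / m.sum(axis=1)
        recall = 100.0 * diag / m.sum(axis=0)
    accuracy = 100.0 * float(diag.sum() / m.sum()) if m.sum() else float("nan")
    return precision, recall, accuracy
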