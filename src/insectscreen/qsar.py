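"""Random-forest QSAR classification with an applicability domain.

The ligand-based arm of the screen: a random-forest classifier trained on a
compounds x descriptors matrix (3D descriptor blocks of the GETAWAY / WHIM /
RDF families, or any numeric feature set), evaluated with the standard
confusion-matrix rates plus the Matthews correlation coefficient and the
area under the ROC curve, and guarded by a Euclidean-distance applicability
domain:

    APD = d_bar + Z * sigma

where d_bar and sigma are the mean and standard deviation of the retained
training pairwise Euclidean distances (those no larger than their grand
mean) and Z is an empirical cutoff, 0.5 by default. A query is in-domain
when its nearest training neighbour lies within APD.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .curation import Label, LabeledCompound

DEFAULT_N_TREES = 250
DEFAULT_Z = 0.5
DEFAULT_PROBABILITY_CUTOFF = 0.5


class QsarError(ValueError):
    """Invalid input to a QSAR operation."""


# ---------------------------------------------------------------------------
# descriptor matrix


@dataclass(frozen=True)
class DescriptorMatrix:
    """Dense compounds x descriptors feature matrix.

    Rows follow ``compound_ids``, columns follow ``descriptor_names``.
    Values must be finite; constant-valued columns are detected so they can
    be dropped before model fitting.
    """

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise QsarError("descriptor values must be a 2-D matrix")
        if values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise QsarError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise QsarError("duplicate compound_id in descriptor matrix")
        if not np.isfinite(values).all():
            bad = [
                self.compound_ids[i]
                for i in np.unique(np.nonzero(~np.isfinite(values))[0])
            ]
            raise QsarError(f"non-finite descriptor values for compounds: {bad}")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def constant_columns(self) -> list[str]:
        """Names of zero-variance descriptor columns."""
        if self.values.shape[0] == 0:
            return []
        mask = np.ptp(self.values, axis=0) == 0.0
        return [n for n, m in zip(self.descriptor_names, mask) if m]

    def drop_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        drop = set(names)
        keep = [i for i, n in enumerate(self.descriptor_names) if n not in drop]
        return DescriptorMatrix(
            compound_ids=self.compound_ids,
            descriptor_names=tuple(self.descriptor_names[i] for i in keep),
            values=self.values[:, keep],
        )

    def subset(self, compound_ids: Sequence[str]) -> "DescriptorMatrix":
        """Row subset in the given order."""
        index = {cid: i for i, cid in enumerate(self.compound_ids)}
        try:
            rows = [index[cid] for cid in compound_ids]
        except KeyError as exc:
            raise QsarError(f"compound {exc.args[0]!r} not in descriptor matrix") from exc
        return DescriptorMatrix(
            compound_ids=tuple(compound_ids),
            descriptor_names=self.descriptor_names,
            values=self.values[rows],
        )


def read_descriptor_matrix(stream: str | io.TextIOBase) -> DescriptorMatrix:
    """Read a descriptor CSV: first column compound_id, the rest numeric."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, dtype={0: str})
    if df.shape[1] < 2:
        raise QsarError("descriptor CSV needs compound_id plus at least one descriptor")
    first = df.columns[0]
    if first != "compound_id":
        raise QsarError(f"first column must be 'compound_id', got {first!r}")
    values = df.drop(columns=[first]).to_numpy(dtype=float)
    return DescriptorMatrix(
        compound_ids=tuple(df[first].astype(str)),
        descriptor_names=tuple(df.columns[1:]),
        values=values,
    )


def write_descriptor_matrix(matrix: DescriptorMatrix) -> str:
    df = pd.DataFrame(matrix.values, columns=list(matrix.descriptor_names))
    df.insert(0, "compound_id", list(matrix.compound_ids))
    return df.to_csv(index=False)


# ---------------------------------------------------------------------------
# stratified partitioning


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test partition specification."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise QsarError(f"train_fraction must lie in (0,1), got {self.train_fraction}")


def stratified_split(
    labeled: Sequence[LabeledCompound], spec: SplitSpec
) -> tuple[list[LabeledCompound], list[LabeledCompound]]:
    """Seeded stratified partition into train and test sets.

    Per class, the test size is round-half-even of ``(1-train_fraction) *
    class_size``; class members are shuffled deterministically by the seed
    before slicing. Each class must end up represented in both halves.
    """
    by_class: dict[Label, list[LabeledCompound]] = {Label.ACTIVE: [], Label.INACTIVE: []}
    for lc in labeled:
        by_class[lc.label].append(lc)
    if not by_class[Label.ACTIVE] or not by_class[Label.INACTIVE]:
        raise QsarError("stratified split requires both classes to be present")
    rng = np.random.default_rng(spec.seed)
    train: list[LabeledCompound] = []
    test: list[LabeledCompound] = []
    for label in (Label.ACTIVE, Label.INACTIVE):
        members = by_class[label]
        n_test = round((1.0 - spec.train_fraction) * len(members))
        if n_test == 0 or n_test == len(members):
            raise QsarError(
                f"split leaves the {label.value} class empty on one side "
                f"(class size {len(members)}, test size {n_test})"
            )
        order = rng.permutation(len(members))
        test.extend(members[i] for i in order[:n_test])
        train.extend(members[i] for i in order[n_test:])
    return train, test


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion matrix: true/false positives and negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise QsarError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise QsarError("confusion matrix must contain at least one prediction")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def matthews_cc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); +1 is a perfect
    forecast, 0 a random one, -1 total disagreement. When any marginal
    factor is zero the coefficient is undefined and 0 (the random-forecast
    value) is returned.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _rate(num: int, den: int) -> float:
    return float("nan") if den == 0 else num / den


@dataclass(frozen=True)
class PerformanceReport:
    """Classification quality summary for one evaluation."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    mcc: float
    auc: float
    counts: ConfusionCounts

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, auc: float) -> "PerformanceReport":
        return cls(
            sensitivity=_rate(counts.tp, counts.tp + counts.fn),
            specificity=_rate(counts.tn, counts.tn + counts.fp),
            accuracy=_rate(counts.tp + counts.tn, counts.total),
            ppv=_rate(counts.tp, counts.tp + counts.fp),
            npv=_rate(counts.tn, counts.tn + counts.fn),
            mcc=matthews_cc(counts),
            auc=auc,
            counts=counts,
        )

    def to_json(self) -> str:
        payload = {
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "accuracy": round(self.accuracy, 4),
            "ppv": round(self.ppv, 4),
            "npv": round(self.npv, 4),
            "mcc": round(self.mcc, 4),
            "auc": round(self.auc, 4),
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def compute_roc(
    scores: Sequence[float], labels: Sequence[Label]
) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC by Mann-Whitney pair counting.

    AUC = (concordant active/inactive pairs + 0.5 * tied pairs) /
    (n_active * n_inactive). The returned curve is an (n, 2) array of
    (FPR, TPR) points, monotone in both axes; its trapezoidal area equals
    the pair-counting AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lbl is Label.ACTIVE else 0 for lbl in labels])
    if scores.shape[0] != y.shape[0]:
        raise QsarError("scores and labels differ in length")
    n_act = int(y.sum())
    n_inact = int((1 - y).sum())
    if n_act == 0 or n_inact == 0:
        raise QsarError("ROC analysis requires at least one compound per class")
    # pair counting via a vectorized comparison (n_act * n_inact pairs)
    a = scores[y == 1][:, None]
    b = scores[y == 0][None, :]
    concordant = float((a > b).sum())
    tied = float((a == b).sum())
    auc = (concordant + 0.5 * tied) / (n_act * n_inact)
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])
    return curve, auc


@dataclass
class ClassifierModel:
    """Trained random-forest activity classifier.

    Wraps a scikit-learn forest and exposes the per-compound probability of
    the active class; identical training inputs and seed give identical
    probabilities.
    """

    estimator: RandomForestClassifier
    descriptor_names: tuple[str, ...]
    n_trees: int
    seed: int

    def predict_proba_active(self, matrix: DescriptorMatrix) -> np.ndarray:
        if matrix.descriptor_names != self.descriptor_names:
            raise QsarError("descriptor columns do not match the trained model")
        classes = list(self.estimator.classes_)
        col = classes.index(1)
        return self.estimator.predict_proba(matrix.values)[:, col]

    def feature_importances(self) -> pd.Series:
        """Impurity-based importance per descriptor, descending."""
        return pd.Series(
            self.estimator.feature_importances_, index=list(self.descriptor_names)
        ).sort_values(ascending=False)


def _encode_labels(labels: Sequence[Label]) -> np.ndarray:
    return np.asarray([1 if lbl is Label.ACTIVE else 0 for lbl in labels])


def train_forest(
    train_matrix: DescriptorMatrix,
    labels: Sequence[Label],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the random-forest classifier (default 250 trees, one seed).

    Constant descriptor columns carry no signal and are dropped with a
    warning before fitting.
    """
    if n_trees < 1:
        raise QsarError(f"n_trees must be >= 1, got {n_trees}")
    if train_matrix.n_compounds == 0:
        raise QsarError("cannot train on an empty descriptor matrix")
    if len(labels) != train_matrix.n_compounds:
        raise QsarError(
            f"{len(labels)} labels do not align with {train_matrix.n_compounds} matrix rows"
        )
    constant = train_matrix.constant_columns()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant descriptor column(s): {constant[:5]}...",
            stacklevel=2,
        )
        train_matrix = train_matrix.drop_columns(constant)
    est = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(train_matrix.values, _encode_labels(labels))
    return ClassifierModel(
        estimator=est,
        descriptor_names=train_matrix.descriptor_names,
        n_trees=n_trees,
        seed=seed,
    )


def counts_from_probabilities(
    probs: Sequence[float],
    labels: Sequence[Label],
    cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> ConfusionCounts:
    """Threshold active-class probabilities at the cutoff (>= is active)."""
    probs = np.asarray(probs, dtype=float)
    y = _encode_labels(labels)
    pred = probs >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def evaluate(
    model: ClassifierModel,
    test_matrix: DescriptorMatrix,
    labels: Sequence[Label],
    probability_cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> PerformanceReport:
    """Score the model on a labelled test matrix."""
    if test_matrix.n_compounds == 0:
        raise QsarError("cannot evaluate on an empty test set")
    if len(labels) != test_matrix.n_compounds:
        raise QsarError("test labels do not align with matrix rows")
    probs = model.predict_proba_active(test_matrix)
    counts = counts_from_probabilities(probs, labels, probability_cutoff)
    _, auc = compute_roc(probs, labels)
    return PerformanceReport.from_counts(counts, auc)


def cross_validate(
    labeled: Sequence[LabeledCompound],
    matrix: DescriptorMatrix,
    k: int = 10,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    probability_cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> PerformanceReport:
    """Stratified k-fold cross-validation, scored on pooled predictions.

    Out-of-fold probabilities from every fold are pooled into a single
    confusion matrix and a single ROC, giving one report for the whole
    procedure. Deterministic under the seed.
    """
    if k < 2:
        raise QsarError(f"cross-validation needs k >= 2 folds, got {k}")
    labels = [lc.label for lc in labeled]
    ids = [lc.record.compound_id for lc in labeled]
    if list(matrix.compound_ids) != ids:
        matrix = matrix.subset(ids)
    y = _encode_labels(labels)
    smallest = min(int(y.sum()), int((1 - y).sum()))
    if smallest == 0:
        raise QsarError("cross-validation requires both classes")
    if k > smallest:
        raise QsarError(f"k={k} exceeds the smallest class size ({smallest})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(labeled), dtype=float)
    for train_idx, test_idx in skf.split(matrix.values, y):
        fold_model = train_forest(
            matrix.subset([ids[i] for i in train_idx]),
            [labels[i] for i in train_idx],
            n_trees=n_trees,
            seed=seed,
        )
        pooled[test_idx] = fold_model.predict_proba_active(
            matrix.subset([ids[i] for i in test_idx])
        )
    counts = counts_from_probabilities(pooled, labels, probability_cutoff)
    _, auc = compute_roc(pooled, labels)
    return PerformanceReport.from_counts(counts, auc)


# ---------------------------------------------------------------------------
# applicability domain


@dataclass(frozen=True)
class DomainModel:
    """Euclidean applicability domain fitted on training descriptors."""

    reference_points: np.ndarray
    d_bar: float
    sigma: float
    z: float

    @property
    def apd_threshold(self) -> float:
        return self.d_bar + self.z * self.sigma


def fit_apd(train_matrix: DescriptorMatrix, z: float = DEFAULT_Z) -> DomainModel:
    """Fit the applicability-domain threshold APD = d_bar + Z * sigma.

    All training pairwise Euclidean distances are computed, distances no
    larger than their grand mean are retained, and d_bar / sigma are the
    mean and (population) standard deviation of the retained subset.
    """
    points = np.asarray(train_matrix.values, dtype=float)
    if points.shape[0] < 2:
        raise QsarError("applicability domain needs at least 2 training compounds")
    dists = pdist(points)
    grand_mean = dists.mean()
    retained = dists[dists <= grand_mean]
    return DomainModel(
        reference_points=points.copy(),
        d_bar=float(retained.mean()),
        sigma=float(retained.std()),
        z=z,
    )


def is_in_domain(domain: DomainModel, query: Sequence[float]) -> bool:
    """True iff the query's nearest-neighbour distance is within APD.

    Boundary equality counts as in-domain.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != domain.reference_points.shape[1]:
        raise QsarError(
            f"query has {q.shape[1]} descriptors, domain expects "
            f"{domain.reference_points.shape[1]}"
        )
    nearest = cdist(q, domain.reference_points).min()
    return bool(nearest <= domain.apd_threshold)


__all__ = [
    "DEFAULT_N_TREES",
    "DEFAULT_PROBABILITY_CUTOFF",
    "DEFAULT_Z",
    "ClassifierModel",
    "ConfusionCounts",
    "DescriptorMatrix",
    "DomainModel",
    "PerformanceReport",
    "QsarError",
    "SplitSpec",
    "compute_roc",
    "counts_from_probabilities",
    "cross_validate",
    "evaluate",
    "fit_apd",
    "is_in_domain",
    "matthews_cc",
    "read_descriptor_matrix",
    "stratified_split",
    "train_forest",
    "write_descriptor_matrix",
]
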