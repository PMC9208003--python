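"""Support-vector classification of vector summaries.

The protocol: a stratified 60/40 train/test split, an RBF-kernel
support-vector classifier with default regularisation in one-vs-one
multiclass mode, held-out accuracy, a confusion matrix and fivefold
cross-validation scores on the training portion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, \
    train_test_split
from sklearn.svm import SVC

from .digraph import Digraph
from .encoding import BinSpec, featurise, vector_summary
from .selection import SelectionSpec, parameter_table, select_neighbourhoods

__all__ = [
    "LabelledDataset",
    "ClassificationReport",
    "split_dataset",
    "train_and_score",
    "run_experiment",
]


@dataclass(frozen=True)
class LabelledDataset:
    vectors: np.ndarray  # N x (M*K)
    labels: np.ndarray  # N class symbols

    def __post_init__(self):
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if self.vectors.shape[0] != self.labels.shape[0]:
            raise ValueError("vectors and labels must align")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    cv_scores: tuple[float, ...]
    confusion: np.ndarray
    classes: tuple
    seed: int
    selection_code: str | None = None
    feature_code: str | None = None
    m: int | None = None
    k: int | None = None

    @property
    def cv_range(self) -> tuple[float, float]:
        if not self.cv_scores:
            return (float("nan"), float("nan"))
        return (min(self.cv_scores), max(self.cv_scores))

    def to_json(self) -> str:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        d["classes"] = [str(c) for c in self.classes]
        return json.dumps(d, indent=2)

    def write_confusion_csv(self, path) -> None:
        """Class-by-class confusion counts (rows = true class)."""
        with open(path, "w") as fh:
            fh.write("true\\pred," + ",".join(str(c) for c in self.classes))
            fh.write("\n")
            for cls, row in zip(self.classes, self.confusion):
                fh.write(f"{cls}," + ",".join(str(int(x)) for x in row) + "\n")


def split_dataset(
    ds: LabelledDataset, train_fraction: float = 0.6, seed: int = 0
) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified train/test split, reproducible by seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = np.unique(ds.labels, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 instances to split")
    xtr, xte, ytr, yte = train_test_split(
        ds.vectors,
        ds.labels,
        train_size=train_fraction,
        random_state=seed,
        stratify=ds.labels,
    )
    return LabelledDataset(xtr, ytr), LabelledDataset(xte, yte)


def _make_svc(seed: int) -> SVC:
    return SVC(
        kernel="rbf", decision_function_shape="ovo", random_state=seed
    )


def train_and_score(
    train: LabelledDataset,
    test: LabelledDataset,
    seed: int = 0,
    cv_folds: int = 5,
    **report_fields,
) -> ClassificationReport:
    """Fit the RBF support-vector classifier and report held-out accuracy,
    the confusion matrix, and fivefold cross-validation on the train set."""
    if len(train.classes) < 2:
        raise ValueError("training set needs at least 2 classes")
    clf = _make_svc(seed)
    clf.fit(train.vectors, train.labels)
    pred = clf.predict(test.vectors)
    accuracy = float(np.mean(pred == test.labels))
    labels_all = np.unique(np.concatenate([train.labels, test.labels]))
    conf = confusion_matrix(test.labels, pred, labels=labels_all)
    min_count = int(np.unique(train.labels, return_counts=True)[1].min())
    folds = min(cv_folds, min_count)  # stratified CV needs folds <= class size
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = cross_val_score(
            _make_svc(seed), train.vectors, train.labels, cv=cv
        )
    else:
        scores = np.array([])
    return ClassificationReport(
        accuracy=accuracy,
        cv_scores=tuple(float(s) for s in scores),
        confusion=conf,
        classes=tuple(labels_all.tolist()),
        seed=seed,
        **report_fields,
    )


def build_dataset(
    dynamics,
    nbhds,
    bins: BinSpec,
    feature_code: str,
    flag_cap: int = 3,
    selection_code: str | None = None,
) -> LabelledDataset:
    """Featurise every dynamics instance into its vector summary."""
    vectors = np.stack([
        vector_summary(
            featurise(
                d, nbhds, bins, feature_code,
                flag_cap=flag_cap, selection_code=selection_code,
                instance_id=i,
            )
        )
        for i, d in enumerate(dynamics)
    ])
    labels = np.asarray([d.label for d in dynamics])
    return LabelledDataset(vectors, labels)


def run_experiment(
    g: Digraph,
    dynamics,
    spec: SelectionSpec,
    feature_code: str,
    bins: BinSpec,
    seed: int = 0,
    flag_cap: int = 3,
    train_fraction: float = 0.6,
    table=None,
    nbhds=None,
) -> ClassificationReport:
    """The full pipeline: select -> featurise -> split -> train and score.

    A precomputed parameter table or neighbourhood list may be passed to
    avoid repeating the per-vertex sweep across experiments.
    """
    if nbhds is None:
        if table is None:
            table = parameter_table(g, [spec.parameter], flag_cap=flag_cap)
        nbhds = select_neighbourhoods(g, spec, table)
    ds = build_dataset(
        dynamics, nbhds, bins, feature_code,
        flag_cap=flag_cap, selection_code=spec.parameter,
    )
    train, test = split_dataset(ds, train_fraction, seed)
    return train_and_score(
        train, test, seed=seed,
        selection_code=spec.parameter, feature_code=feature_code,
        m=len(nbhds), k=bins.num_bins,
    )
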