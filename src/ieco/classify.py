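"""Diagnostic classification of subject color fingerprints.

Implements the discriminative protocol: a small CNN on the K x 1 RGB
strips, a logistic (GLM) baseline on the 3K integrated network features
(42 features for the default 14-network atlas), and a logistic baseline
on mean framewise displacement alone.  Each diagnostic group is compared
against the reference group on a single held-out 80/20 split and scored
by the area under the precision-recall curve (PR-AUC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from ._cnn import TinyCnn
from .encoding import METRICS, FeatureTable, SubjectColorImage

__all__ = [
    "SplitSpec",
    "CnnSpec",
    "ClassifierReport",
    "assemble_dataset",
    "assemble_image_dataset",
    "pr_auc",
    "train_cnn",
    "train_glm",
]


@dataclass
class SplitSpec:
    """A single train/test partition (the protocol uses one 80/20 split,
    not cross-validation; repeated splits only to gauge dispersion)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def split(self, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx,
            train_size=self.train_fraction,
            random_state=self.seed,
            stratify=y if self.stratified else None,
        )
        for part, name in ((tr, "train"), (te, "test")):
            if len(np.unique(y[part])) < 2:
                raise ValueError(
                    f"class absent from the {name} partition; use a stratified split "
                    "or more subjects"
                )
        return tr, te


@dataclass
class CnnSpec:
    """CNN hyperparameters.  The architecture (1x3 window, dense-4,
    sigmoid output, adam, binary cross-entropy) is fixed; filter count,
    epochs and batch size are free parameters."""

    n_filters: int = 8
    dense_units: int = 4
    window: int = 3
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0


@dataclass
class ClassifierReport:
    model: str  # cnn | glm_features | glm_motion
    comparison: Tuple[str, str]  # (diagnosis, reference)
    split: SplitSpec
    test_subjects: List[str]
    test_scores: List[float]
    test_targets: List[int]
    pr_recall: List[float]
    pr_precision: List[float]
    pr_auc: float
    notes: str = ""

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        d = asdict(self)
        d["comparison"] = list(self.comparison)
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ClassifierReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["comparison"] = tuple(d["comparison"])
        d["split"] = SplitSpec(**d["split"])
        return cls(**d)


def _select_two_groups(groups: Sequence[str], comparison: Tuple[str, str]) -> np.ndarray:
    diagnosis, reference = comparison
    if diagnosis == reference:
        raise ValueError(f"degenerate comparison {comparison}: only one class")
    groups = np.asarray(groups)
    sel = np.isin(groups, [diagnosis, reference])
    for g in comparison:
        if not (groups == g).any():
            raise ValueError(f"group {g} has no subjects")
    return sel


def assemble_dataset(
    table: FeatureTable,
    comparison: Tuple[str, str],
    scaled: bool = False,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """GLM design matrix: the 3K (metric x network) feature columns,
    diagnosis coded 1 and reference 0."""
    src = table.scaled if scaled else table.data
    if scaled and table.scaled is None:
        raise ValueError("table has not been scaled")
    sel = _select_two_groups(src["group"], comparison)
    sub = src.loc[sel]
    cols = [c for m in METRICS for c in table.metric_columns(m)]
    X = sub[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = sub.loc[np.isnan(X).any(axis=1), "subject_id"].tolist()
        raise ValueError(f"subjects with missing features: {bad}")
    y = (sub["group"] == comparison[0]).to_numpy(dtype=int)
    return X, y, sub["subject_id"].tolist()


def assemble_image_dataset(
    images: Sequence[SubjectColorImage],
    comparison: Tuple[str, str],
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """CNN inputs: (n, K, 3) stacks of 8-bit strips, diagnosis coded 1."""
    groups = [im.group for im in images]
    if any(g is None for g in groups):
        bad = [im.subject_id for im in images if im.group is None]
        raise ValueError(f"images without a group label: {bad}")
    sel = _select_two_groups(groups, comparison)
    kept = [im for im, s in zip(images, sel) if s]
    X = np.stack([im.pixels.astype(float) for im in kept])
    y = np.array([int(im.group == comparison[0]) for im in kept])
    return X, y, [im.subject_id for im in kept]


def pr_auc(scores: np.ndarray, targets: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its area by step-wise summation.

    Thresholds sweep the distinct score values in descending order, ties
    grouped; the area is sum over thresholds of (R_i - R_{i-1}) * P_i
    (average-precision style, no interpolation).  Returns (recall,
    precision, area); the returned curve is prepended with the recall-0
    anchor and always ends at recall 1.
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if scores.shape != targets.shape or scores.ndim != 1:
        raise ValueError("scores and targets must be equal-length 1D arrays")
    P = int(targets.sum())
    if P == 0 or P == len(targets):
        raise ValueError("need at least one positive and one negative target")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = targets[order]
    # indices where a threshold ends (last element of each tie block)
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(t)[ends]
    fp = np.cumsum(1 - t)[ends]
    recall = tp / P
    precision = tp / (tp + fp)
    area = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return recall, precision, area


def train_cnn(
    images: Sequence[SubjectColorImage],
    comparison: Tuple[str, str],
    spec: Optional[CnnSpec] = None,
    split: Optional[SplitSpec] = None,
) -> ClassifierReport:
    """Train the CNN on the train partition, score the held-out subjects."""
    spec = spec or CnnSpec()
    split = split or SplitSpec()
    X, y, sids = assemble_image_dataset(images, comparison)
    tr, te = split.split(y)
    model = TinyCnn(
        n_bands=X.shape[1],
        n_channels=X.shape[2],
        n_filters=spec.n_filters,
        dense_units=spec.dense_units,
        window=spec.window,
        learning_rate=spec.learning_rate,
        seed=spec.seed,
    )
    model.fit(X[tr], y[tr], epochs=spec.epochs, batch_size=spec.batch_size, seed=spec.seed)
    scores = model.predict_proba(X[te])
    rec, prec, auc = pr_auc(scores, y[te])
    return ClassifierReport(
        model="cnn",
        comparison=tuple(comparison),
        split=split,
        test_subjects=[sids[i] for i in te],
        test_scores=[float(v) for v in scores],
        test_targets=[int(v) for v in y[te]],
        pr_recall=list(map(float, rec)),
        pr_precision=list(map(float, prec)),
        pr_auc=auc,
    )


def train_glm(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Optional[Sequence[str]] = None,
    comparison: Tuple[str, str] = ("case", "control"),
    split: Optional[SplitSpec] = None,
    ridge: float = 0.0,
    model_name: str = "glm_features",
) -> ClassifierReport:
    """Logistic regression baseline on a feature matrix (or a single
    mean-FD column).  ``ridge=0`` fits plain maximum likelihood; under
    perfect separation the fit cannot converge and a minimal ridge
    penalty is applied automatically and recorded in the report.
    Features are standardised on the train partition (the logistic MLE
    is invariant to affine feature rescaling)."""
    split = split or SplitSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(y))]
    tr, te = split.split(y)

    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    notes = ""
    if ridge > 0:
        clf = LogisticRegression(C=1.0 / ridge, max_iter=2000)
        clf.fit(Xs[tr], y[tr])
    else:
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(Xs[tr], y[tr])
        diverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        # a hyperplane that classifies the training set perfectly means the
        # data is separable and the unpenalised MLE does not exist
        margin = clf.decision_function(Xs[tr])
        separated = bool(np.all((2 * y[tr] - 1) * margin > 0))
        if diverged or separated:
            min_ridge = 1e-3
            warnings.warn(
                "unpenalised logistic fit is degenerate (likely perfect "
                f"separation); refitting with minimal ridge {min_ridge}",
                stacklevel=2,
            )
            clf = LogisticRegression(C=1.0 / min_ridge, max_iter=2000)
            clf.fit(Xs[tr], y[tr])
            notes = f"separation detected; minimal ridge {min_ridge} applied"

    scores = clf.predict_proba(Xs[te])[:, 1]
    rec, prec, auc = pr_auc(scores, y[te])
    return ClassifierReport(
        model=model_name,
        comparison=tuple(comparison),
        split=split,
        test_subjects=[subject_ids[i] for i in te],
        test_scores=[float(v) for v in scores],
        test_targets=[int(v) for v in y[te]],
        pr_recall=list(map(float, rec)),
        pr_precision=list(map(float, prec)),
        pr_auc=auc,
        notes=notes,
    )
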