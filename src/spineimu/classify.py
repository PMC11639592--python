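"""Linear-discriminant placement classifier and its deployable export.

Training uses standard LDA on standardized window features.  For deployment
the whole decision path collapses to a scaler plus one linear map:

    p = softmax(W @ (x - mu) / sigma + b),   y = argmax(p)

so the export carries only W, b, mu, sigma, the class labels, and the
feature-name order — everything a mobile runtime needs.  The exported
predictor reproduces the in-memory model's probabilities exactly (LDA's
posterior is the softmax of its decision scores).

Evaluation is subject-wise: subjects are split into train/test groups
(default 9/3) so no person contributes windows to both sides, repeated over
random splits with the scaler and classifier refitted on training subjects
only each time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import softmax
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import InvalidArgumentError
from .features import FeatureMatrix, Scaler, apply_scaler, fit_scaler

__all__ = ["LinearClassifierExport", "EvalReport", "train_lda", "predict",
           "evaluate_subjectwise"]

EXPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LinearClassifierExport:
    """Deployable scaler + linear + softmax predictor."""

    W: np.ndarray             # (l, d)
    b: np.ndarray             # (l,)
    mu: np.ndarray            # (d,)
    sigma: np.ndarray         # (d,)
    class_labels: np.ndarray  # (l,) location codes
    feature_names: list[str]

    def __post_init__(self) -> None:
        l, d = self.W.shape
        if not (self.b.shape == (l,) and self.mu.shape == (d,)
                and self.sigma.shape == (d,) and len(self.class_labels) == l
                and len(self.feature_names) == d):
            raise InvalidArgumentError("export dimensions are inconsistent")
        for a in (self.W, self.b, self.mu, self.sigma):
            if not np.all(np.isfinite(a)):
                raise InvalidArgumentError("non-finite export parameters")

    def to_json(self, path: str | Path) -> None:
        # json round-trips Python floats bit-faithfully (shortest repr)
        Path(path).write_text(json.dumps({
            "version": EXPORT_SCHEMA_VERSION,
            "class_labels": self.class_labels.tolist(),
            "feature_names": self.feature_names,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearClassifierExport":
        d = json.loads(Path(path).read_text())
        if d.get("version") != EXPORT_SCHEMA_VERSION:
            raise InvalidArgumentError(
                f"unsupported export schema version {d.get('version')!r}"
            )
        return cls(
            W=np.asarray(d["W"], float),
            b=np.asarray(d["b"], float),
            mu=np.asarray(d["mu"], float),
            sigma=np.asarray(d["sigma"], float),
            class_labels=np.asarray(d["class_labels"]),
            feature_names=list(d["feature_names"]),
        )


@dataclass
class EvalReport:
    """Subject-wise evaluation summary."""

    split_accuracies: list[float]
    mean_accuracy: float
    per_class_accuracy: dict
    confusion: np.ndarray          # (l, l), rows = true class, row-stochastic
    class_labels: np.ndarray
    splits: list[dict]             # train/test subject ids per split
    leakage_flag: bool = False     # feature ranking saw test subjects

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "split_accuracies": self.split_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "confusion": self.confusion.tolist(),
            "class_labels": self.class_labels.tolist(),
            "splits": self.splits,
            "leakage_flag": self.leakage_flag,
        }, indent=2))


def train_lda(X: FeatureMatrix, seed: int = 0, return_model: bool = False):
    """Fit the scaler and LDA on training rows and bundle the export.

    The fit itself is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic stages.  Falls back to a shrinkage
    (Ledoit-Wolf) solver with a warning when the within-class scatter is
    singular — likely with 84 correlated features over short windows.
    """
    if X.labels is None:
        raise InvalidArgumentError("train_lda needs a labeled FeatureMatrix")
    if len(np.unique(X.labels)) < 2:
        raise InvalidArgumentError("need at least 2 classes")
    scaler = fit_scaler(X)
    Z = apply_scaler(X.X, scaler)
    # pooled within-class scatter; singular when features are collinear
    Sw = np.zeros((Z.shape[1], Z.shape[1]))
    for c in np.unique(X.labels):
        Zc = Z[X.labels == c]
        Zc = Zc - Zc.mean(axis=0)
        Sw += Zc.T @ Zc
    ev = np.linalg.eigvalsh(Sw)
    if ev[0] <= 1e-10 * max(ev[-1], 1e-300):
        warnings.warn("within-class scatter is singular; fitting with "
                      "shrinkage (lsqr, Ledoit-Wolf)", stacklevel=2)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(Z, X.labels)
    else:
        lda = LinearDiscriminantAnalysis(solver="svd").fit(Z, X.labels)
    W = np.asarray(lda.coef_, float)
    b = np.asarray(lda.intercept_, float)
    if len(lda.classes_) == 2:
        # sklearn stores one row for binary problems; expand to the two-row
        # form so softmax(scores) equals the binary posterior (sigmoid)
        W = np.vstack([np.zeros_like(W[0]), W[0]])
        b = np.array([0.0, b[0]])
    export = LinearClassifierExport(
        W=W,
        b=b,
        mu=scaler.mu,
        sigma=scaler.sigma,
        class_labels=np.asarray(lda.classes_),
        feature_names=list(X.feature_names),
    )
    if return_model:
        return export, lda, scaler
    return export


def predict(x: np.ndarray, m: LinearClassifierExport):
    """Class probabilities and label(s) for raw (unscaled) feature vector(s).

    Accepts a single d-vector or an (n, d) batch.  Ties in the argmax go to
    the lowest class index.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    d = m.W.shape[1]
    if X.shape[1] != d:
        raise InvalidArgumentError(f"expected {d} features, got {X.shape[1]}")
    scores = ((X - m.mu) / m.sigma) @ m.W.T + m.b
    p = softmax(scores, axis=1)
    y = m.class_labels[np.argmax(p, axis=1)]
    if single:
        return p[0], y[0]
    return p, y


def _split_subjects(subjects: np.ndarray, n_train: int, n_splits: int, seed: int):
    rng = np.random.default_rng(seed)
    for _ in range(n_splits):
        perm = rng.permutation(subjects)
        yield set(perm[:n_train]), set(perm[n_train:])


def evaluate_subjectwise(
    X: FeatureMatrix,
    n_train_subjects: int = 9,
    n_splits: int = 10,
    seed: int = 0,
    selected_features: list[str] | None = None,
    ranked_on_full_data: bool = True,
) -> EvalReport:
    """Repeated random subject-wise train/test evaluation.

    Per split the scaler and LDA are fitted on training subjects only; the
    feature subset, when supplied, is typically ranked on the full dataset
    (set ``ranked_on_full_data=False`` if it was derived from training data
    only) — the report's ``leakage_flag`` records this.

    Accuracy is the fraction of correctly classified windows; the confusion
    matrix is normalized by true class and averaged over splits.
    """
    if X.labels is None or X.groups is None:
        raise InvalidArgumentError("evaluation needs labels and subject groups")
    subjects = np.unique(X.groups)
    if len(subjects) < n_train_subjects + 1:
        raise InvalidArgumentError(
            f"{len(subjects)} subjects cannot support {n_train_subjects} "
            "training subjects plus a test set"
        )
    Xs = X.select(selected_features) if selected_features is not None else X
    classes = np.unique(Xs.labels)
    l = len(classes)
    accs, confs, split_defs = [], [], []
    for train_subj, test_subj in _split_subjects(subjects, n_train_subjects,
                                                 n_splits, seed):
        tr = np.isin(Xs.groups, list(train_subj))
        te = ~tr
        model = train_lda(Xs.rows(tr))
        _, y_hat = predict(Xs.X[te], model)
        y_true = Xs.labels[te]
        accs.append(float(np.mean(y_hat == y_true)))
        C = np.zeros((l, l))
        for i, ct in enumerate(classes):
            row_mask = y_true == ct
            for j, cp in enumerate(classes):
                C[i, j] = np.mean(y_hat[row_mask] == cp) if row_mask.any() else 0.0
        confs.append(C)
        split_defs.append({"train": sorted(map(str, train_subj)),
                           "test": sorted(map(str, test_subj))})
    confusion = np.mean(confs, axis=0)
    return EvalReport(
        split_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        per_class_accuracy={int(c): float(confusion[i, i])
                            for i, c in enumerate(classes)},
        confusion=confusion,
        class_labels=classes,
        splits=split_defs,
        leakage_flag=bool(selected_features is not None and ranked_on_full_data),
    )
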