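"""Linear discriminant analysis on amino-acid composition vectors.

Dehydrin orders differ systematically in composition (e.g. Tyr/Thr enrichment
in Y-order, Phe in F-order, His/Lys in H-order sequences), so classical LDA
on the 20 composition fractions separates them well.  This is the textbook
formulation: class means, pooled within-class covariance with a small ridge
on the diagonal (composition vectors live on a simplex, so the covariance is
rank-deficient without it), discriminant axes from the generalized
eigenproblem of between- versus within-class scatter, and Gaussian
equal-covariance discriminant scores with empirical class priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass
class LdaModel:
    classes: np.ndarray          # (k,) class labels, sorted
    means: np.ndarray            # (k, d) per-class feature means
    priors: np.ndarray           # (k,) empirical priors, sum to 1
    covariance: np.ndarray       # (d, d) pooled within-class, ridge-regularized
    scalings: np.ndarray         # (d, m) discriminant axes, m <= k - 1
    grand_mean: np.ndarray       # (d,)
    dropped_feature: int | None = None

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]


def _prepare(x, drop_feature: int | None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D sample-by-feature matrix")
    if drop_feature is not None:
        x = np.delete(x, drop_feature, axis=1)
    return x


def fit_lda(
    vectors,
    labels,
    ridge: float = 1e-6,
    drop_feature: int | None = None,
) -> LdaModel:
    """Fit classical LDA with a ridge-regularized pooled covariance.

    ``drop_feature`` removes one column before fitting, an optional way to
    lift the sum-to-one degeneracy of compositional inputs (the ridge alone
    is normally sufficient).
    """
    x = _prepare(vectors, drop_feature)
    y = np.asarray(labels)
    if len(y) != len(x):
        raise ValueError("labels and vectors disagree in length")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    n, d = x.shape
    k = len(classes)
    counts = np.bincount(y_idx, minlength=k)
    if counts.min() < 2:
        raise ValueError("every class needs more than one sample")
    means = np.vstack([x[y_idx == c].mean(axis=0) for c in range(k)])
    priors = counts / n
    grand_mean = x.mean(axis=0)

    sw = np.zeros((d, d))
    for c in range(k):
        dev = x[y_idx == c] - means[c]
        sw += dev.T @ dev
    sw /= n - k
    sw += ridge * np.eye(d)

    sb = np.zeros((d, d))
    for c in range(k):
        dm = (means[c] - grand_mean)[:, None]
        sb += counts[c] * (dm @ dm.T)
    sb /= n

    try:
        eigvals, eigvecs = scipy.linalg.eigh(sb, sw)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular even after regularization; "
            "increase the ridge epsilon"
        ) from exc
    order = np.argsort(eigvals)[::-1][: k - 1]
    scalings = eigvecs[:, order]
    return LdaModel(
        classes=classes, means=means, priors=priors, covariance=sw,
        scalings=scalings, grand_mean=grand_mean,
        dropped_feature=drop_feature,
    )


def transform(model: LdaModel, vectors) -> np.ndarray:
    """Project samples onto the discriminant axes (LD1, LD2, ...)."""
    x = _prepare(vectors, model.dropped_feature)
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"expected {model.means.shape[1]} features, got {x.shape[1]}"
        )
    return (x - model.grand_mean) @ model.scalings


def predict(model: LdaModel, vectors) -> tuple[np.ndarray, pd.DataFrame]:
    """Class labels plus per-class discriminant scores and LD coordinates.

    Scores are the Gaussian equal-covariance discriminants
    delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c; the argmax
    class wins.
    """
    x = _prepare(vectors, model.dropped_feature)
    if x.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"expected {model.means.shape[1]} features, got {x.shape[1]}"
        )
    sinv_mu = np.linalg.solve(model.covariance, model.means.T)  # (d, k)
    scores = (
        x @ sinv_mu
        - 0.5 * np.sum(model.means.T * sinv_mu, axis=0)
        + np.log(model.priors)
    )
    labels = model.classes[np.argmax(scores, axis=1)]
    coords = transform(model, vectors)
    out = pd.DataFrame(
        scores, columns=[f"score_{c}" for c in model.classes]
    )
    for i in range(min(2, coords.shape[1])):
        out[f"LD{i + 1}"] = coords[:, i]
    out["predicted"] = labels
    return labels, out


def accuracy_report(
    model: LdaModel, vectors, labels
) -> dict[str, object]:
    """Overall accuracy, per-class recall and the confusion matrix."""
    y = np.asarray(labels)
    predicted, _ = predict(model, vectors)
    overall = float((predicted == y).mean())
    confusion = pd.DataFrame(
        _sk_confusion(y, predicted, labels=model.classes),
        index=model.classes, columns=model.classes,
    )
    per_class = {}
    for cls in model.classes:
        sel = y == cls
        per_class[str(cls)] = float((predicted[sel] == cls).mean()) if sel.any() else float("nan")
    return {
        "overall_accuracy": overall,
        "per_class_recall": per_class,
        "confusion": confusion,
    }


def cross_validate(
    vectors, labels, k_folds: int = 5, seed: int = 0, ridge: float = 1e-6
) -> float:
    """Mean k-fold cross-validated accuracy (extension to the resubstitution
    report)."""
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, k_folds)
    accs = []
    for i in range(k_folds):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k_folds) if j != i])
        model = fit_lda(x[train], y[train], ridge=ridge)
        predicted, _ = predict(model, x[test])
        accs.append(float((predicted == y[test]).mean()))
    return float(np.mean(accs))
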