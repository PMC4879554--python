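"""PC-LDA classification engine: PCA, significant-component selection,
linear discriminant analysis on PC scores, leave-one-out cross-validation,
frozen-model prediction and confusion-matrix summaries.

The workflow mirrors standard chemometric practice for vibrational
spectra: spectra (already derivative-preprocessed and vector-normalized)
are compressed by PCA; the principal components whose scores differ
significantly between groups (one-way ANOVA, p < alpha) are kept, capped
at fewer than half the size of the smallest group to avoid over-fitting;
LDA is then fitted in the selected-PC score space and spectra are
assigned to the nearest class mean in discriminant space (equal priors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import f_oneway
from sklearn.decomposition import PCA

from .spectra_io import SpectrumSet

__all__ = [
    "PCAModel",
    "FactorSelection",
    "LDAModel",
    "PCLDAModel",
    "ConfusionMatrix",
    "fit_pca",
    "project",
    "group_size_factor_cap",
    "select_significant_pcs",
    "fit_lda",
    "fit_pclda",
    "loocv",
    "predict",
    "classification_efficiency",
]

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Mean-centred PCA basis on a common wavenumber grid."""

    mean_vector: np.ndarray
    loadings: np.ndarray            # (n_factors, n_points), orthonormal rows
    explained_variance: np.ndarray  # per-factor, non-increasing
    axis: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[0]


def fit_pca(sset: SpectrumSet, n_factors: int = 10) -> PCAModel:
    """Fit mean-centred PCA with ``n_factors`` components.

    Requires at least 2 spectra on a common axis and
    ``n_factors <= min(n_spectra - 1, n_points)``.
    """
    X = sset.matrix()
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    bound = min(n - 1, p)
    if not (1 <= n_factors <= bound):
        raise ValueError(f"n_factors must be in [1, {bound}] for {n} spectra x {p} points")
    pca = PCA(n_components=n_factors, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        mean_vector=pca.mean_,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_,
        axis=np.asarray(sset.common_axis),
    )


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project (n, p) data onto the PCA basis, returning (n, n_factors) scores."""
    return (np.atleast_2d(X) - model.mean_vector) @ model.loadings.T


# ---------------------------------------------------------------------------
# Factor selection

def group_size_factor_cap(group_sizes) -> int:
    """Over-fitting guard: the largest integer strictly below min(sizes)/2.

    E.g. smallest group 16 -> cap 7; 45 -> 22; 4 -> 1.
    """
    sizes = list(group_sizes)
    if not sizes:
        raise ValueError("group_sizes is empty")
    if min(sizes) < 2:
        raise ValueError("every group must have at least 2 spectra")
    m = min(sizes)
    return (m - 1) // 2


@dataclass
class FactorSelection:
    """Outcome of significance screening of PC scores."""

    selected_indices: list[int]     # 0-based, sorted ascending
    p_values: np.ndarray            # one per candidate factor
    alpha: float
    max_factors: int


def select_significant_pcs(
    scores: np.ndarray, labels, alpha: float = 0.05, cap: int | None = None
) -> FactorSelection:
    """Keep factors whose scores separate the groups (one-way ANOVA p < alpha).

    If more than ``cap`` factors qualify, the ``cap`` smallest p-values
    win, ties broken by lower factor index; the returned indices are
    sorted ascending.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups to screen factors")
    for g in uniq:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 spectra; F-test undefined")
    scores = np.atleast_2d(scores)
    n_factors = scores.shape[1]
    pvals = np.empty(n_factors)
    for j in range(n_factors):
        per_group = [scores[labels == g, j] for g in uniq]
        if all(np.ptp(col) == 0 for col in per_group) and len({c[0] for c in per_group}) == 1:
            pvals[j] = 1.0  # constant factor: no evidence of separation
            continue
        pvals[j] = f_oneway(*per_group).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    significant = [j for j in range(n_factors) if pvals[j] < alpha]
    if cap is None:
        cap = n_factors
    if len(significant) > cap:
        significant = sorted(sorted(significant, key=lambda j: (pvals[j], j))[:cap])
    return FactorSelection(
        selected_indices=sorted(significant),
        p_values=pvals,
        alpha=alpha,
        max_factors=cap,
    )


# ---------------------------------------------------------------------------
# LDA in selected-PC space

@dataclass
class LDAModel:
    """Multi-class LDA: discriminant axes and class means in discriminant space.

    Axes are eigenvectors of the generalized problem S_b v = lambda S_w v,
    scaled so the pooled within-class covariance is whitened; nearest
    class mean under the Euclidean metric in this space is then the
    maximum-discriminant-score rule with equal priors.
    """

    class_labels: list[str]
    discriminant_axes: np.ndarray  # (n_axes, n_selected_features)
    class_means: np.ndarray        # (n_classes, n_axes), in discriminant space
    feature_means: np.ndarray      # overall mean in selected-PC space


def fit_lda(scores: np.ndarray, labels) -> LDAModel:
    """Fit within/between-scatter LDA on (n, k) selected-PC scores."""
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    n, k = scores.shape
    n_classes = len(classes)
    if n_classes < 2:
        raise ValueError("LDA needs at least 2 classes")
    overall = scores.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    means = np.empty((n_classes, k))
    for i, c in enumerate(classes):
        Xc = scores[labels == c]
        mc = Xc.mean(axis=0)
        means[i] = mc
        d = Xc - mc
        Sw += d.T @ d
        diff = (mc - overall)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise ValueError(
            "within-class scatter is singular; use fewer PCA factors"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(k, n_classes - 1)
    W = evecs[:, order[:n_axes]].T          # rows satisfy w S_w w^T = 1
    # Rescale so the pooled covariance S_w/(n - C) is whitened: Euclidean
    # distance in discriminant space = Mahalanobis wrt pooled covariance.
    W = W * np.sqrt(max(n - n_classes, 1))
    class_means_d = (means - overall) @ W.T
    return LDAModel(
        class_labels=[str(c) for c in classes],
        discriminant_axes=W,
        class_means=class_means_d,
        feature_means=overall,
    )


def _lda_transform(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(scores) - model.feature_means) @ model.discriminant_axes.T


def lda_predict(model: LDAModel, scores: np.ndarray) -> list[str]:
    """Nearest class mean in discriminant space; ties -> lowest class index."""
    Z = _lda_transform(model, scores)
    d2 = ((Z[:, None, :] - model.class_means[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return [model.class_labels[i] for i in idx]


# ---------------------------------------------------------------------------
# Confusion matrices

@dataclass
class ConfusionMatrix:
    """Square per-group classification counts (rows true, columns predicted)."""

    labels: list[str]
    counts: np.ndarray
    kind: str = "training"  # training | loocv | test

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, true_labels, pred_labels, labels, kind: str = "training"):
        labels = [str(label) for label in labels]
        index = {label: i for i, label in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true_labels, pred_labels):
            counts[index[str(t)], index[str(p)]] += 1
        return cls(labels=labels, counts=counts, kind=kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def classification_efficiency(cm: ConfusionMatrix) -> dict:
    """Percent correctly classified: overall (100*trace/total) and per group."""
    rows = cm.row_sums
    if np.any(rows == 0):
        raise ValueError("every true group must contain at least one spectrum")
    diag = np.diag(cm.counts)
    return {
        "overall": 100.0 * diag.sum() / cm.total,
        "per_group": {
            label: 100.0 * diag[i] / rows[i] for i, label in enumerate(cm.labels)
        },
    }


# ---------------------------------------------------------------------------
# PC-LDA

@dataclass
class PCLDAModel:
    """Frozen standard model: PCA basis + factor selection + LDA."""

    pca: PCAModel
    selection: FactorSelection
    lda: LDAModel
    training_meta: dict = field(default_factory=dict)

    @property
    def class_labels(self) -> list[str]:
        return self.lda.class_labels

    def to_json(self, path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "axis": self.pca.axis.tolist(),
            "mean_vector": self.pca.mean_vector.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "explained_variance": self.pca.explained_variance.tolist(),
            "selected_indices": self.selection.selected_indices,
            "p_values": self.selection.p_values.tolist(),
            "alpha": self.selection.alpha,
            "max_factors": self.selection.max_factors,
            "class_labels": self.lda.class_labels,
            "discriminant_axes": self.lda.discriminant_axes.tolist(),
            "class_means": self.lda.class_means.tolist(),
            "feature_means": self.lda.feature_means.tolist(),
            "training_meta": self.training_meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "PCLDAModel":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {doc.get('format_version')}")
        pca = PCAModel(
            mean_vector=np.asarray(doc["mean_vector"]),
            loadings=np.asarray(doc["loadings"]),
            explained_variance=np.asarray(doc["explained_variance"]),
            axis=np.asarray(doc["axis"]),
        )
        selection = FactorSelection(
            selected_indices=list(doc["selected_indices"]),
            p_values=np.asarray(doc["p_values"]),
            alpha=doc["alpha"],
            max_factors=doc["max_factors"],
        )
        lda = LDAModel(
            class_labels=list(doc["class_labels"]),
            discriminant_axes=np.asarray(doc["discriminant_axes"]),
            class_means=np.asarray(doc["class_means"]),
            feature_means=np.asarray(doc["feature_means"]),
        )
        return cls(pca=pca, selection=selection, lda=lda, training_meta=doc["training_meta"])


def fit_pclda(sset: SpectrumSet, n_pca_factors: int = 10, alpha: float = 0.05) -> PCLDAModel:
    """Fit the full PC-LDA chain on a preprocessed SpectrumSet.

    PCA (``n_pca_factors``) -> score projection -> group-size factor cap ->
    ANOVA significance selection -> LDA in selected-PC space.
    """
    labels = sset.labels
    sizes = sset.group_sizes()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if min(sizes.values()) < 3:
        raise ValueError("every group needs at least 3 spectra")
    # clamp to the PCA-admissible bound so small (e.g. toy/LOOCV-fold)
    # sets work with the standard 10-factor default
    n_used = min(n_pca_factors, len(sset) - 1, sset.matrix().shape[1])
    pca = fit_pca(sset, n_used)
    scores = project(pca, sset.matrix())
    cap = group_size_factor_cap(sizes.values())
    selection = select_significant_pcs(scores, labels, alpha=alpha, cap=cap)
    if not selection.selected_indices:
        # Nothing passes the screen (e.g. label-permuted null data): fall
        # back to the single best-separating factor so a model — at
        # chance level — can still be built and cross-validated.
        best = int(np.argmin(selection.p_values))
        selection = FactorSelection(
            selected_indices=[best],
            p_values=selection.p_values,
            alpha=alpha,
            max_factors=cap,
        )
    lda = fit_lda(scores[:, selection.selected_indices], labels)
    return PCLDAModel(
        pca=pca,
        selection=selection,
        lda=lda,
        training_meta={
            "group_sizes": {str(k): int(v) for k, v in sizes.items()},
            "n_pca_factors": n_pca_factors,
            "alpha": alpha,
            "factor_cap": cap,
        },
    )


def predict(model: PCLDAModel, sset: SpectrumSet, kind: str = "test"):
    """Classify spectra with a frozen model.

    Each spectrum is centred with the model's training mean, projected on
    the selected loadings and assigned by the nearest-class-mean rule.
    Returns ``(labels, confusion_matrix_or_None)``; the confusion matrix
    (over the model's class labels) is built when the set carries true
    group labels that are all known to the model.
    """
    if sset.common_axis is None or sset.common_axis.shape != model.pca.axis.shape or not np.allclose(
        sset.common_axis, model.pca.axis
    ):
        raise ValueError(
            "axis mismatch: spectra must be preprocessed onto the model grid "
            f"[{model.pca.axis[0]:g}..{model.pca.axis[-1]:g}] "
            f"({model.pca.axis.size} points)"
        )
    scores = project(model.pca, sset.matrix())
    pred = lda_predict(model.lda, scores[:, model.selection.selected_indices])
    true = sset.labels
    cm = None
    if all(t in model.class_labels for t in true):
        cm = ConfusionMatrix.from_labels(true, pred, model.class_labels, kind=kind)
    return pred, cm


def loocv(sset: SpectrumSet, n_pca_factors: int = 10, alpha: float = 0.05) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the entire PC-LDA pipeline.

    For every spectrum the whole chain — PCA, significance selection, LDA
    — is refitted on the remaining n-1 spectra before the held-out
    spectrum is predicted, so no information leaks from the test fold.
    """
    n = len(sset)
    all_labels = [str(g) for g in sset.groups]
    true: list[str] = []
    pred: list[str] = []
    for i in range(n):
        train = sset.subset([j for j in range(n) if j != i])
        try:
            model = fit_pclda(train, n_pca_factors=n_pca_factors, alpha=alpha)
        except ValueError as exc:
            raise ValueError(f"LOOCV fold {i} (held out {sset.spectra[i].spectrum_id!r}): {exc}") from exc
        scores = project(model.pca, sset.spectra[i].intensities[None, :])
        p = lda_predict(model.lda, scores[:, model.selection.selected_indices])[0]
        true.append(sset.spectra[i].group)
        pred.append(p)
    return ConfusionMatrix.from_labels(true, pred, all_labels, kind="loocv")
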