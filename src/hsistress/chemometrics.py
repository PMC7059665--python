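"""PCA feature extraction / score imaging and chemometric dataset splitting.

:class:`SpectralPCA` is a centering-only principal component analysis
(reflectance bands share units, so no variance scaling) with a fixed sign
convention — each loading's largest-magnitude element is positive — so
score images are reproducible across runs.  Ten components are the default
feature set for classification.

Dataset splitting follows chemometric practice: the Kennard-Stone
algorithm ranks samples by coverage of the spectral space, either to pick
a 2:1 calibration/prediction split or, per class, to deal samples
round-robin into training/validation/test at 4:1:1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import PixelSpectra

__all__ = [
    "SpectralPCA", "DatasetSplit",
    "fit_pca", "transform_pca", "score_image",
    "kennard_stone_order", "kennard_stone_split", "split_4_1_1",
    "save_pca", "load_pca",
]


class SpectralPCA(TransformerMixin, BaseEstimator):
    """Centering-only PCA via singular value decomposition.

    Parameters
    ----------
    n_components : int
        Number of components kept; must not exceed ``min(n_samples - 1,
        n_features)``.

    Attributes
    ----------
    mean_ : (n_features,) band-wise training mean.
    components_ : (n_components, n_features) orthonormal loadings, ordered
        by explained variance, sign-fixed so each row's largest-magnitude
        entry is positive.
    explained_variance_ratio_ : per-component fraction of total variance.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 samples")
        k = self.n_components
        if k < 1 or k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} out of range for {n} samples x {p} features "
                f"(max {min(n - 1, p)})")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        total = float((s**2).sum())
        if total <= 1e-24:
            raise ValueError("degenerate data: zero variance in every direction")
        # sign convention: largest-|.| element of each loading is positive
        flip = np.sign(vt[np.arange(vt.shape[0]),
                          np.argmax(np.abs(vt), axis=1)])
        vt = vt * flip[:, None]
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (s[:k] ** 2) / total
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} bands, model was fit with "
                f"{self.n_features_in_}")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return np.asarray(scores) @ self.components_ + self.mean_

    @property
    def loadings(self) -> np.ndarray:
        """(n_features, n_components) loading matrix."""
        check_is_fitted(self, "components_")
        return self.components_.T


def fit_pca(X: np.ndarray, k: int) -> SpectralPCA:
    return SpectralPCA(n_components=k).fit(X)


def transform_pca(model: SpectralPCA, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


def score_image(px: PixelSpectra, model: SpectralPCA, pc_index: int,
                shape: tuple[int, int]) -> np.ndarray:
    """2-D map of each pixel's score on one component (1-based index).

    Background (unmasked) pixels are NaN.
    """
    if not (1 <= pc_index <= model.components_.shape[0]):
        raise ValueError(
            f"pc_index={pc_index} out of range 1..{model.components_.shape[0]}")
    if px.coords.size and (px.coords[:, 0].max() >= shape[0]
                           or px.coords[:, 1].max() >= shape[1]):
        raise ValueError("pixel coordinates fall outside the image shape")
    scores = model.transform(px.spectra)[:, pc_index - 1]
    img = np.full(shape, np.nan)
    img[px.coords[:, 0], px.coords[:, 1]] = scores
    return img


def render_score_images(px: PixelSpectra, model: SpectralPCA,
                        shape: tuple[int, int], path,
                        n_components: int | None = None) -> None:
    """Write a pseudo-color panel of the first components' score images."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import pyplot as plt

    k = n_components or model.components_.shape[0]
    ncol = min(5, k)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow))
    for idx, ax in enumerate(np.atleast_1d(axes).ravel()):
        if idx < k:
            im = ax.imshow(score_image(px, model, idx + 1, shape),
                           cmap="viridis", interpolation="nearest")
            ax.set_title(f"PC{idx + 1}", fontsize=8)
            fig.colorbar(im, ax=ax, fraction=0.046)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def kennard_stone_order(X: np.ndarray) -> np.ndarray:
    """Full Kennard-Stone ranking of samples.

    Starts from the two samples at maximal Euclidean distance, then
    repeatedly adds the sample whose minimum distance to the selected set
    is largest.  Ties break toward the lowest index; deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    D = cdist(X, X)
    if D.max() <= 0.0:
        raise ValueError("degenerate data: all pairwise distances are zero")
    i, j = np.unravel_index(np.argmax(D), D.shape)  # row-major -> lowest index
    order = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[order] = False
    min_d = np.minimum(D[order[0]], D[order[1]])
    while remaining.any():
        cand = np.where(remaining, min_d, -np.inf)
        nxt = int(np.argmax(cand))  # argmax takes the first (lowest index) on ties
        order.append(nxt)
        remaining[nxt] = False
        min_d = np.minimum(min_d, D[nxt])
    return np.array(order)


def kennard_stone_split(X: np.ndarray, calibration_fraction: float = 2 / 3
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone calibration/prediction split (default 2:1)."""
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must be in (0, 1)")
    order = kennard_stone_order(X)
    n = len(order)
    n_cal = int(np.ceil(calibration_fraction * n))
    cal = np.sort(order[:n_cal])
    pred = np.sort(order[n_cal:])
    return cal, pred


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index sets covering all samples."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split subsets overlap")

    @property
    def n_samples(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


# round-robin deal pattern for the 4:1:1 ratio
_DEAL_PATTERN = ("train", "train", "train", "train", "validation", "test")


def split_4_1_1(labels: np.ndarray, X: np.ndarray) -> DatasetSplit:
    """Per-class 4:1:1 train/validation/test split by Kennard-Stone rank.

    Within each class, samples are ranked by the Kennard-Stone algorithm
    and dealt round-robin as train,train,train,train,validation,test; all
    three subsets therefore sample the class's spectral extremes.
    Deterministic given ``X``.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    if len(labels) != len(X):
        raise ValueError("labels and X length mismatch")
    buckets: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) < 6:
            raise ValueError(
                f"class {cls} has only {len(idx)} samples; the 4:1:1 split "
                "needs at least 6 per class")
        order = kennard_stone_order(X[idx])
        for rank, local in enumerate(order):
            buckets[_DEAL_PATTERN[rank % 6]].append(int(idx[local]))
    return DatasetSplit(np.sort(buckets["train"]),
                        np.sort(buckets["validation"]),
                        np.sort(buckets["test"]))


def save_pca(model: SpectralPCA, path: str | Path) -> None:
    """Serialize a fitted PCA to a flat text file."""
    check_is_fitted(model, "components_")
    with open(path, "w") as fh:
        fh.write(f"n_components: {model.components_.shape[0]}\n")
        fh.write(f"n_features: {model.n_features_in_}\n")
        fh.write("mean: " + " ".join(f"{v:.17g}" for v in model.mean_) + "\n")
        fh.write("explained_variance_ratio: "
                 + " ".join(f"{v:.17g}" for v in model.explained_variance_ratio_)
                 + "\n")
        fh.write("singular_values: "
                 + " ".join(f"{v:.17g}" for v in model.singular_values_) + "\n")
        for row in model.components_:
            fh.write("component: " + " ".join(f"{v:.17g}" for v in row) + "\n")


def load_pca(path: str | Path) -> SpectralPCA:
    lines = Path(path).read_text().splitlines()
    fields: dict[str, list[str]] = {}
    components = []
    for line in lines:
        key, _, value = line.partition(":")
        if key == "component":
            components.append([float(v) for v in value.split()])
        else:
            fields[key] = value.split()
    model = SpectralPCA(n_components=int(fields["n_components"][0]))
    model.components_ = np.array(components)
    model.mean_ = np.array([float(v) for v in fields["mean"]])
    model.explained_variance_ratio_ = np.array(
        [float(v) for v in fields["explained_variance_ratio"]])
    model.singular_values_ = np.array(
        [float(v) for v in fields["singular_values"]])
    model.n_features_in_ = int(fields["n_features"][0])
    return model
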