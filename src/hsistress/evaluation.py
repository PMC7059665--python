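"""Classification metrics and pixel-wise prediction maps.

Accuracy and unweighted Cohen's kappa are computed from 3x3 confusion
matrices over the treatment categories CK=1, Q=2, S=3.  Prediction maps
push every plant pixel of a reflectance cube through the fixed
preprocessing chain, project it onto the fitted principal components and
classify it, yielding a label image and per-category pixel fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn.metrics

from .chemometrics import SpectralPCA
from .hypercube import HyperCube
from .preprocessing import (BAND_HI_NM, BAND_LO_NM, MA_WINDOW, WAVELET,
                            WAVELET_LEVEL, extract_pixel_spectra,
                            preprocess_pixel_spectra)
from .svc import RBFSupportVectorClassifier
from .synthetic import TREATMENT_LABELS

__all__ = [
    "ConfusionMatrix", "PredictionMap",
    "confusion_matrix", "accuracy", "cohen_kappa",
    "prediction_map", "pixel_summary",
]


@dataclass
class ConfusionMatrix:
    """Integer counts, rows = actual, columns = predicted."""

    counts: np.ndarray
    labels: tuple = TREATMENT_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(actual, predicted,
                     labels: tuple = TREATMENT_LABELS) -> ConfusionMatrix:
    """counts[i, j] = number of samples with actual label i, predicted j."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted")
    if len(actual) == 0:
        raise ValueError("empty label sequences")
    known = set(labels)
    unknown = (set(np.unique(actual)) | set(np.unique(predicted))) - known
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}; expected {labels}")
    counts = sklearn.metrics.confusion_matrix(actual, predicted,
                                              labels=list(labels))
    return ConfusionMatrix(counts, labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa, (p_o - p_e) / (1 - p_e).

    ``p_e`` is the chance agreement implied by the row/column marginals.
    Undefined (raises) when all mass sits in a single cell (p_e = 1).
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / n**2
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: chance agreement p_e = 1 "
                         "(all mass in one cell)")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class PredictionMap:
    """Per-pixel label image (0 = background) with category fractions."""

    label_image: np.ndarray
    fractions: dict
    true_label: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-10:
            raise ValueError(f"category fractions sum to {total}, not 1")

    @property
    def majority_label(self) -> int:
        # dict preserves label order CK,Q,S; max is stable toward CK on ties
        return max(self.fractions, key=self.fractions.get)


def prediction_map(cube: HyperCube, mask: np.ndarray, pca: SpectralPCA,
                   model: RBFSupportVectorClassifier,
                   true_label: int | None = None, *,
                   lo_nm: float = BAND_LO_NM, hi_nm: float = BAND_HI_NM,
                   wavelet: str = WAVELET, level: int = WAVELET_LEVEL,
                   window: int = MA_WINDOW) -> PredictionMap:
    """Classify every plant pixel of a reflectance cube.

    Each masked pixel's spectrum runs through crop/denoise/smooth, is
    projected onto the PCA features the classifier was trained on, and is
    assigned a treatment label.  Background pixels get label 0.
    """
    if not hasattr(model, "machines_"):
        raise ValueError("classifier is not fitted")
    if not hasattr(pca, "components_"):
        raise ValueError("PCA model is not fitted")
    px = extract_pixel_spectra(cube, mask)
    px = preprocess_pixel_spectra(px, lo_nm, hi_nm, wavelet, level, window)
    labels = model.predict(pca.transform(px.spectra))
    image = np.zeros(mask.shape, dtype=int)
    image[px.coords[:, 0], px.coords[:, 1]] = labels
    n = len(labels)
    fractions = {int(lab): float((labels == lab).sum()) / n
                 for lab in TREATMENT_LABELS}
    return PredictionMap(image, fractions, true_label=true_label)


def pixel_summary(maps_by_group: dict) -> pd.DataFrame:
    """Mean +/- sd of predicted-category pixel fractions per true treatment.

    ``maps_by_group`` maps each true label to its list of prediction maps.
    Returns a table with one row per true treatment and mean/sd columns
    per predicted category.
    """
    rows = []
    for group in sorted(maps_by_group):
        maps = maps_by_group[group]
        if not maps:
            raise ValueError(f"no prediction maps for group {group}")
        fr = np.array([[m.fractions[lab] for lab in TREATMENT_LABELS]
                       for m in maps])
        row = {"true_label": group, "n_maps": len(maps)}
        for k, lab in enumerate(TREATMENT_LABELS):
            row[f"mean_frac_{lab}"] = float(fr[:, k].mean())
            row[f"sd_frac_{lab}"] = float(fr[:, k].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)
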