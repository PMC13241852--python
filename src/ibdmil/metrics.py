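"""Multiclass evaluation metrics and attention-map rendering.

The evaluation report mirrors the standard slide-classification
suite: accuracy, macro and weighted F1, per-class F1, per-class
one-vs-rest AUC (midrank tie handling), and the confusion matrix with
truth on rows.  A class absent from the truth gets an undefined AUC,
excluded from macro averaging with a warning.

Attention maps paint each kept patch's footprint with its attention
weight into a downscaled slide-space raster; cells outside kept
patches are NaN so renderers can distinguish "no patch" from "zero
attention".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score as _sk_auc

from .grouping import GroupingScheme


@dataclass
class EvalReport:
    """Slide-level classification metrics for one evaluation run."""

    accuracy: float
    macro_f1: float
    weighted_f1: float
    per_class_f1: list[float]
    per_class_auc: list[Optional[float]]
    confusion: np.ndarray  # (K, K), rows = truth
    n_per_class: list[int]
    grouping: Optional[str] = None
    condition: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class_f1": self.per_class_f1,
            "per_class_auc": self.per_class_auc,
            "confusion": self.confusion.tolist(),
            "n_per_class": self.n_per_class,
            "grouping": self.grouping,
            "condition": self.condition,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_frame(self, class_names: Sequence[str] | None = None) -> pd.DataFrame:
        k = len(self.confusion)
        names = list(class_names) if class_names else [str(i) for i in range(k)]
        return pd.DataFrame(self.confusion, index=names, columns=names)


def compute_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    probabilities: Optional[np.ndarray],
    n_classes: int,
    *,
    grouping: Optional[str] = None,
    condition: Optional[str] = None,
) -> EvalReport:
    """Compute the full evaluation report.

    ``probabilities`` rows must sum to 1 (within 1e-6) when given;
    omit them to skip AUC.  F1 with an empty denominator is defined as
    0.  Per-class AUC is one-vs-rest; for a class with no positive or
    no negative examples in the truth it is ``None`` (undefined) and
    excluded from any averaging, with a warning.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions must align")
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(truth), n_classes):
            raise ValueError("probabilities must be (n_samples, n_classes)")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    labels = list(range(n_classes))
    cm = _sk_confusion(truth, predicted, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    per_f1 = _sk_f1(truth, predicted, labels=labels, average=None, zero_division=0)
    macro_f1 = float(np.mean(per_f1))
    support = cm.sum(axis=1)
    weighted_f1 = (
        float(np.average(per_f1, weights=support)) if support.sum() else 0.0
    )

    per_auc: list[Optional[float]] = []
    if probabilities is not None:
        for c in labels:
            pos = truth == c
            if pos.all() or not pos.any():
                warnings.warn(
                    f"class {c} has no positives or no negatives in truth; AUC undefined",
                    stacklevel=2,
                )
                per_auc.append(None)
            else:
                per_auc.append(float(_sk_auc(pos.astype(int), probabilities[:, c])))
    else:
        per_auc = [None] * n_classes

    return EvalReport(
        accuracy=accuracy,
        macro_f1=macro_f1,
        weighted_f1=weighted_f1,
        per_class_f1=[float(v) for v in per_f1],
        per_class_auc=per_auc,
        confusion=cm,
        n_per_class=[int(v) for v in support],
        grouping=grouping,
        condition=condition,
    )


def regroup_predictions(
    truth: np.ndarray, predicted: np.ndarray, scheme: GroupingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse five-grade truth/prediction pairs through a grouping."""
    m = np.asarray(scheme.mapping)
    return m[np.asarray(truth, dtype=int)], m[np.asarray(predicted, dtype=int)]


# ---------------------------------------------------------------------------
# Attention rendering
# ---------------------------------------------------------------------------


@dataclass
class AttentionMap:
    """Slide-space raster of per-patch attention weights."""

    slide_id: str
    raster: np.ndarray  # float, NaN outside kept patches
    downscale: int
    patch_origins: np.ndarray  # (n, 2) slide pixels
    patch_size: int
    weights: np.ndarray  # (n,)
    predicted_class: Optional[int] = None
    probabilities: Optional[np.ndarray] = None

    def top_patches(self, k: int = 5) -> pd.DataFrame:
        order = np.argsort(-self.weights)[:k]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "row": self.patch_origins[order, 0],
                "col": self.patch_origins[order, 1],
                "weight": self.weights[order],
            }
        )

    def save_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.raster.astype(np.float32))


def render_attention(
    slide_id: str,
    patch_origins: np.ndarray | Sequence[tuple[int, int]],
    weights: np.ndarray,
    slide_dims: tuple[int, int],
    patch_size: int,
    downscale: int = 16,
    *,
    predicted_class: Optional[int] = None,
    probabilities: Optional[np.ndarray] = None,
) -> AttentionMap:
    """Paint each patch footprint with its attention weight.

    Patch footprints are half-open ``[row, row+patch_size)`` squares in
    slide space, scaled down by ``downscale`` into the raster.  Patches
    whose footprint exceeds the slide bounds raise, listing offenders.
    Footprints never overlap by construction of the patch grid.
    """
    origins = np.asarray(patch_origins, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if len(origins) != len(weights):
        raise ValueError("origins and weights must align")
    sh, sw = slide_dims
    bad = [
        i
        for i, (r, c) in enumerate(origins)
        if r < 0 or c < 0 or r + patch_size > sh or c + patch_size > sw
    ]
    if bad:
        raise ValueError(f"patch origins out of slide bounds at indices {bad[:10]}")

    raster = np.full((-(-sh // downscale), -(-sw // downscale)), np.nan)
    for (r, c), w in zip(origins, weights):
        r0, c0 = r // downscale, c // downscale
        r1 = -(-(r + patch_size) // downscale)
        c1 = -(-(c + patch_size) // downscale)
        raster[r0:r1, c0:c1] = w
    return AttentionMap(
        slide_id=slide_id,
        raster=raster,
        downscale=downscale,
        patch_origins=origins,
        patch_size=patch_size,
        weights=weights,
        predicted_class=predicted_class,
        probabilities=probabilities,
    )
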