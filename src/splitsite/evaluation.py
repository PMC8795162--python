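"""Metrics and the feature-map privacy audit.

Metrics: classification accuracy (percent, threshold 0.5 with ">= predicts
positive"), binary cross-entropy, MSE, and RMSLE
``sqrt(mean((ln(1+pred) - ln(1+actual))^2))``.

The privacy audit quantifies what the study demonstrates visually: how much
of an input image survives in the transmitted feature map.  Two scores are
reported, without pass/fail thresholds:

- per-channel maximum absolute Pearson correlation between the bilinearly
  upsampled channel and the input image;
- normalized RMSE of the best least-squares linear reconstruction of the
  image from the upsampled channels (1.0 means no better than predicting the
  mean pixel; 0.0 means perfect linear inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage.transform import resize

from .nn import loss_value

__all__ = [
    "MetricResult",
    "PrivacyReport",
    "accuracy",
    "rmsle",
    "binary_crossentropy",
    "mse",
    "audit_leakage",
]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    n: int
    higher_is_better: bool

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.name} is not finite")
        if self.name == "accuracy" and not 0.0 <= self.value <= 100.0:
            raise ValueError("accuracy must be a percentage in [0, 100]")
        if self.name == "rmsle" and self.value < 0:
            raise ValueError("RMSLE must be >= 0")


def accuracy(predicted: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> MetricResult:
    """Percent of correct thresholded predictions; ``p >= threshold`` is 1."""
    p = np.asarray(predicted, dtype=float).reshape(-1)
    y = np.asarray(labels).reshape(-1)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    value = 100.0 * float(np.mean((p >= threshold).astype(int) == y))
    return MetricResult("accuracy", value, p.size, higher_is_better=True)


def rmsle(predicted: np.ndarray, actual: np.ndarray) -> MetricResult:
    """Root mean squared logarithmic error with the standard 1+x shift."""
    p = np.asarray(predicted, dtype=float).reshape(-1)
    a = np.asarray(actual, dtype=float).reshape(-1)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if (p <= -1).any() or (a <= -1).any():
        raise ValueError("RMSLE requires all values > -1")
    value = float(np.sqrt(np.mean((np.log1p(p) - np.log1p(a)) ** 2)))
    return MetricResult("rmsle", value, p.size, higher_is_better=False)


def binary_crossentropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean BCE; probabilities epsilon-clipped at 1e-7."""
    return loss_value("binary_crossentropy", p, y)


def mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    return loss_value("mse", predicted, actual)


# ---------------------------------------------------------------------------
# privacy audit


@dataclass
class PrivacyReport:
    per_channel_correlation: list[float]
    max_correlation: float
    reconstruction_nrmse: float
    figure_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.per_channel_correlation):
            raise ValueError("correlations must lie in [0, 1]")
        if self.reconstruction_nrmse < 0:
            raise ValueError("reconstruction nRMSE must be >= 0")

    def to_dict(self) -> dict:
        return {
            "per_channel_correlation": self.per_channel_correlation,
            "max_correlation": self.max_correlation,
            "reconstruction_nrmse": self.reconstruction_nrmse,
            "figure_paths": self.figure_paths,
        }


def _safe_abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r|; defined as 0 when either input has zero variance."""
    a = a.reshape(-1)
    b = b.reshape(-1)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return min(abs(r), 1.0)


def audit_leakage(
    input_image: np.ndarray,
    feature_map: np.ndarray,
    figure_path: str | Path | None = None,
) -> PrivacyReport:
    """Score how much of ``input_image`` leaks through ``feature_map``.

    ``input_image`` is 2-D [H, W]; ``feature_map`` is 3-D [h, w, c] as
    produced by a conv+pool client layer.  When ``figure_path`` is given, a
    side-by-side figure (original | first feature-map channel) is exported.
    """
    img = np.asarray(input_image, dtype=float)
    fm = np.asarray(feature_map, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"input image must be 2-D, got shape {img.shape}")
    if fm.ndim != 3:
        raise ValueError(f"feature map must be [h, w, c], got shape {fm.shape}")
    h, w = img.shape

    upsampled = np.stack(
        [
            resize(fm[:, :, c], (h, w), order=1, mode="edge", anti_aliasing=False)
            for c in range(fm.shape[2])
        ],
        axis=-1,
    )
    corrs = [_safe_abs_corr(upsampled[:, :, c], img) for c in range(fm.shape[2])]

    # best linear reconstruction of the image from the upsampled channels
    design = np.concatenate(
        [np.ones((h * w, 1)), upsampled.reshape(h * w, fm.shape[2])], axis=1
    )
    target = img.reshape(-1)
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    residual = target - design @ beta
    baseline = float(np.sqrt(np.mean((target - target.mean()) ** 2)))
    if baseline == 0:
        nrmse = 0.0
    else:
        nrmse = float(np.sqrt(np.mean(residual**2)) / baseline)

    figure_paths: list[str] = []
    if figure_path is not None:
        figure_path = Path(figure_path)
        figure_path.parent.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 2, figsize=(7, 3.5))
        axes[0].imshow(img, cmap="gray")
        axes[0].set_title("original")
        axes[1].imshow(fm[:, :, 0], cmap="gray")
        axes[1].set_title("feature map (channel 1)")
        for ax in axes:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
        figure_paths.append(str(figure_path))

    return PrivacyReport(
        per_channel_correlation=corrs,
        max_correlation=max(corrs) if corrs else 0.0,
        reconstruction_nrmse=nrmse,
        figure_paths=figure_paths,
    )
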