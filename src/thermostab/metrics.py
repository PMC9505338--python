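"""Regression metrics and 3-class melting-temperature binning.

All five measures use population (1/N) normalization. PCC is the
covariance of prediction and truth divided by the product of their
standard deviations; RMSE/MSE/MAE are the usual error means (°C, °C², °C);
R² is 1 − SSres/SStot with SStot taken about the mean of the experimental
values, and may be negative for predictors worse than the constant mean.

The 3-class binning assigns Tm < 55 °C to "low", 55 ≤ Tm < 65 to "mid" and
Tm ≥ 65 to "high" (boundary values fall to the upper category's closed
side, making the partition total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import DataError

#: Class boundaries in °C.
TM_CLASS_BOUNDS = (55.0, 65.0)
TM_CLASS_LABELS = ("low", "mid", "high")


def _pair(y_pred, y_true) -> tuple[np.ndarray, np.ndarray]:
    yp = np.asarray(y_pred, dtype=float).ravel()
    yt = np.asarray(y_true, dtype=float).ravel()
    if yp.shape != yt.shape:
        raise DataError(f"length mismatch: {yp.shape[0]} predictions vs {yt.shape[0]} truths")
    if yp.size == 0:
        raise DataError("empty input")
    if not (np.all(np.isfinite(yp)) and np.all(np.isfinite(yt))):
        raise DataError("non-finite values in input")
    return yp, yt


def pcc(y_pred, y_true) -> float:
    """Pearson correlation coefficient (population covariance / SDs)."""
    yp, yt = _pair(y_pred, y_true)
    if yp.size < 2:
        raise DataError("pcc requires n >= 2")
    dp, dt = yp - yp.mean(), yt - yt.mean()
    vp, vt = np.mean(dp**2), np.mean(dt**2)
    if vp == 0.0 or vt == 0.0:
        raise DataError("pcc undefined for a zero-variance input")
    # single square root keeps pcc(y, y) exactly 1
    return float(np.mean(dp * dt) / np.sqrt(vp * vt))


def mse(y_pred, y_true) -> float:
    """Mean squared error (°C²)."""
    yp, yt = _pair(y_pred, y_true)
    return float(np.mean((yp - yt) ** 2))


def rmse(y_pred, y_true) -> float:
    """Root mean square error (°C)."""
    return float(np.sqrt(mse(y_pred, y_true)))


def mae(y_pred, y_true) -> float:
    """Mean absolute error (°C)."""
    yp, yt = _pair(y_pred, y_true)
    return float(np.mean(np.abs(yp - yt)))


def r2(y_pred, y_true) -> float:
    """Coefficient of determination, 1 − SSres/SStot (≤ 1, may be negative)."""
    yp, yt = _pair(y_pred, y_true)
    if yp.size < 2:
        raise DataError("r2 requires n >= 2")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("r2 undefined for constant experimental values")
    ss_res = float(np.sum((yp - yt) ** 2))
    return 1.0 - ss_res / ss_tot


def tm_class(tm: float) -> str:
    """Bin a melting temperature into low / mid / high."""
    if not np.isfinite(tm):
        raise DataError(f"non-finite Tm: {tm}")
    lo, hi = TM_CLASS_BOUNDS
    if tm < lo:
        return TM_CLASS_LABELS[0]
    if tm < hi:
        return TM_CLASS_LABELS[1]
    return TM_CLASS_LABELS[2]


def class_accuracy(pred_tms, true_tms) -> float:
    """Fraction of records whose predicted and true Tm fall in the same bin."""
    yp, yt = _pair(pred_tms, true_tms)
    matches = sum(tm_class(p) == tm_class(t) for p, t in zip(yp, yt))
    return matches / yp.size


@dataclass
class EvaluationReport:
    """The five regression measures (plus optional 3-class accuracy)."""

    pcc: float
    rmse: float
    mse: float
    mae: float
    r2: float
    n: int
    class_accuracy: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __str__(self) -> str:
        parts = [
            f"PCC={self.pcc:.3f}",
            f"RMSE={self.rmse:.3f} °C",
            f"MSE={self.mse:.3f} °C²",
            f"MAE={self.mae:.3f} °C",
            f"R2={self.r2:.3f}",
            f"n={self.n}",
        ]
        if self.class_accuracy is not None:
            parts.append(f"class_acc={self.class_accuracy:.3f}")
        return "  ".join(parts)


def evaluate(y_pred, y_true, with_classes: bool = False) -> EvaluationReport:
    """Compute all five measures on one prediction set."""
    yp, yt = _pair(y_pred, y_true)
    return EvaluationReport(
        pcc=pcc(yp, yt),
        rmse=rmse(yp, yt),
        mse=mse(yp, yt),
        mae=mae(yp, yt),
        r2=r2(yp, yt),
        n=int(yp.size),
        class_accuracy=class_accuracy(yp, yt) if with_classes else None,
    )
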