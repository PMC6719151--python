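"""Forecast-accuracy indices: RMSE, MAPE, MAD and MAD-MEAN.

All four are computed on paired (actual, predicted) vectors with errors
``e_i = predicted_i - actual_i``:

* RMSE      = sqrt(mean(e^2))            — same units as the data
* MAD       = mean(|e|)                  — same units as the data
* MAPE      = 100 * mean(|e / actual|)   — percent; undefined if any actual is 0
* MAD-MEAN  = 100 * sum(|e|) / sum(actual) — percent; undefined if the
  actuals sum to 0

MAD-MEAN (the total absolute deviation relative to the total level of the
series) doubles as the stopping statistic of the seasonal model's adaptive
node search; both call sites share :func:`mad_mean_index` so the definition
lives in one place.  Undefined indices are reported as ``None`` rather than
raising, so the remaining indices are still usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AccuracyReport", "accuracy", "mad_mean_index"]


@dataclass(frozen=True)
class AccuracyReport:
    """The four accuracy indices for one (actual, predicted) pairing."""

    rmse: float
    mape: float | None
    mad: float
    mad_mean: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mape": self.mape,
            "mad": self.mad,
            "mad_mean": self.mad_mean,
            "n": self.n,
        }


def mad_mean_index(errors, reference) -> float | None:
    """Total absolute error over total reference level, in percent.

    ``errors`` are residuals; ``reference`` holds the values whose sum sets
    the scale (the raw series).  Returns ``None`` when the reference sums to
    zero and the errors do not vanish; an exact fit is 0 regardless.
    """
    errors = np.asarray(errors, dtype=float)
    total_abs = float(np.abs(errors).sum())
    denom = float(np.asarray(reference, dtype=float).sum())
    if denom == 0.0:
        return 0.0 if total_abs == 0.0 else None
    return 100.0 * total_abs / denom


def accuracy(actual, predicted) -> AccuracyReport:
    """Compute RMSE, MAPE, MAD and MAD-MEAN for paired vectors.

    Raises
    ------
    ValueError
        If the vectors are empty or of different lengths.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"actual and predicted must have equal length, got "
            f"{actual.size} and {predicted.size}"
        )
    if actual.size == 0:
        raise ValueError("accuracy requires at least one pair")
    e = predicted - actual
    rmse = float(np.sqrt(np.mean(e * e)))
    mad = float(np.mean(np.abs(e)))
    if (actual == 0.0).any():
        mape: float | None = None
    else:
        with np.errstate(over="ignore"):  # subnormal actuals can overflow
            mape = float(100.0 * np.mean(np.abs(e / actual)))
    return AccuracyReport(
        rmse=rmse,
        mape=mape,
        mad=mad,
        mad_mean=mad_mean_index(e, actual),
        n=int(actual.size),
    )
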