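"""Heat Index: apparent temperature from air temperature and humidity.

The Heat Index (HI) measures the physiological discomfort caused by the
combination of high air temperature and high relative humidity.  It is
computed from the NWS/Rothfusz multiple-regression surface

    HI = c1 + c2*T + c3*RH + c4*T*RH + c5*T^2 + c6*RH^2
       + c7*T^2*RH + c8*T*RH^2 + c9*T^2*RH^2

with T the daily maximum air temperature and RH the relative humidity in
percent.  The regression is only meaningful for hot, humid conditions; this
module applies it when T > 27 degC and RH > 40% and otherwise passes the
temperature through unchanged (HI = T).  The two published rules leave a gap
(e.g. 25-27 degC, or RH between 30% and 40%); passthrough is extended to the
whole non-regression region, and rows falling in the gap are counted and
logged so the choice is visible.

The shipped coefficients are the standard NWS set, stated in degrees
Fahrenheit; Celsius inputs are converted to Fahrenheit for evaluation and
the result converted back.  An alternative coefficient set (e.g. one stated
directly in Celsius) can be supplied via :class:`HICoefficients`.

Not implemented: the NWS adjustment terms for the very-low-RH / very-high-RH
corner cases and the simple Steadman formula used below 80 degF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["HICoefficients", "ROTHFUSZ", "heat_index", "hi_series"]

_T_APPLY_C = 27.0  # regression applies strictly above this temperature
_RH_APPLY = 40.0  # ... and strictly above this relative humidity


@dataclass(frozen=True)
class HICoefficients:
    """The nine regression coefficients, with the unit system they expect.

    Signs are carried by the coefficient values themselves; evaluation is a
    plain signed nine-term sum.
    """

    c: tuple[float, float, float, float, float, float, float, float, float]
    unit_system: str = "fahrenheit"

    def __post_init__(self):
        if len(self.c) != 9:
            raise ValueError("exactly 9 coefficients required")
        if self.unit_system not in ("fahrenheit", "celsius"):
            raise ValueError("unit_system must be 'fahrenheit' or 'celsius'")


#: Standard NWS (Rothfusz) regression coefficients, in degrees Fahrenheit.
ROTHFUSZ = HICoefficients(
    c=(
        -42.379,
        2.04901523,
        10.14333127,
        -0.22475541,
        -6.83783e-3,
        -5.481717e-2,
        1.22874e-3,
        8.5282e-4,
        -1.99e-6,
    ),
    unit_system="fahrenheit",
)


def _regression(t, rh, coeffs: HICoefficients):
    c = coeffs.c
    return (
        c[0]
        + c[1] * t
        + c[2] * rh
        + c[3] * t * rh
        + c[4] * t * t
        + c[5] * rh * rh
        + c[6] * t * t * rh
        + c[7] * t * rh * rh
        + c[8] * t * t * rh * rh
    )


def heat_index(t_c, rh_pct, coefficients: HICoefficients = ROTHFUSZ):
    """Heat index in degC from temperature (degC) and relative humidity (%).

    Applies the regression when ``T > 27`` and ``RH > 40`` (strict on both);
    everywhere else the heat index is the air temperature itself.

    Raises
    ------
    ValueError
        If RH is outside [0, 100] or T outside the plausible [-50, 60] degC.
    """
    t_arr = np.asarray(t_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if ((rh < 0.0) | (rh > 100.0)).any():
        raise ValueError("relative humidity must be within [0, 100] percent")
    if ((t_arr < -50.0) | (t_arr > 60.0)).any():
        raise ValueError("temperature outside plausible range [-50, 60] degC")

    apply = (t_arr > _T_APPLY_C) & (rh > _RH_APPLY)
    if coefficients.unit_system == "fahrenheit":
        t_eval = t_arr * 9.0 / 5.0 + 32.0
        hi_eval = _regression(t_eval, rh, coefficients)
        hi_eval = (hi_eval - 32.0) * 5.0 / 9.0
    else:
        hi_eval = _regression(t_arr, rh, coefficients)
    out = np.where(apply, hi_eval, t_arr)
    if np.isscalar(t_c) and np.isscalar(rh_pct):
        return float(out)
    return out


def hi_series(
    weather: pd.DataFrame, coefficients: HICoefficients = ROTHFUSZ
) -> pd.DataFrame:
    """Heat-index series from daily weather rows.

    ``weather`` needs a time column (``t`` or ``date``, time-ordered) plus
    ``tmax_c`` and ``rh_pct``; rows with missing days are simply absent.
    Returns a frame with the time column and ``hi_c``.  Rows in the gap
    between the two published applicability rules (warm but not hot/humid
    enough for the regression) are counted and logged.
    """
    time_col = "t" if "t" in weather.columns else "date"
    for col in (time_col, "tmax_c", "rh_pct"):
        if col not in weather.columns:
            raise ValueError(f"weather frame is missing column '{col}'")
    if not weather[time_col].is_monotonic_increasing:
        raise ValueError("weather rows must be time-ordered")
    t = weather["tmax_c"].to_numpy(dtype=float)
    rh = weather["rh_pct"].to_numpy(dtype=float)
    try:
        hi = heat_index(t, rh, coefficients)
    except ValueError as exc:
        # locate the first offending row for a useful message
        for i, (ti, ri) in enumerate(zip(t, rh)):
            try:
                heat_index(float(ti), float(ri), coefficients)
            except ValueError:
                raise ValueError(f"row {i}: {exc}") from exc
        raise
    gap = ((t > 25.0) & ~((t > _T_APPLY_C) & (rh > _RH_APPLY))).sum()
    if gap:
        logger.info(
            "%d row(s) in the applicability gap (warm but below the "
            "regression guard); passthrough HI = T used",
            int(gap),
        )
    return pd.DataFrame({time_col: weather[time_col].to_numpy(), "hi_c": hi})
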