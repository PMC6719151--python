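"""Seeded synthetic series with the structure the forecaster assumes.

The generator emulates multi-year blocks of daily summer observations such
as a July-August heat-index record: a slow polynomial trend across years, a
mean-zero within-season fluctuation repeated identically every year, and
additive iid Gaussian noise, with optional independently missing days.  The
ground-truth components are returned alongside the series so every pipeline
stage (trend recovery, seasonal-profile recovery, forecast error versus the
noise floor) has an oracle.

Defaults mirror the intended study design: 15 years of 62-day seasonal
windows (930 slots), a gentle quadratic trend at heat-index-like levels,
a weekly fluctuation of amplitude 2 and noise of sd 0.5.  What the generator
does *not* emulate: autocorrelated noise, drifting seasonal shape, or any
station metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seasonal import TimeSeries, day_of_season

__all__ = ["SimConfig", "default_weekly_profile", "generate_series", "generate_weather"]

_RNG_NAME = "numpy.random.Generator(PCG64)"


def default_weekly_profile(season_length: int = 62, amplitude: float = 2.0) -> np.ndarray:
    """Mean-zero weekly fluctuation tiled over one seasonal window.

    A 7-day sinusoid of the given amplitude, repeated across the window and
    re-centred so the profile sums to zero (the additive trend/seasonal
    split is only identifiable with a mean-zero seasonal part).
    """
    d = np.arange(season_length)
    profile = amplitude * np.sin(2.0 * np.pi * (d % 7) / 7.0)
    return profile - profile.mean()


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    ``trend_coeffs`` are polynomial coefficients in the normalised time
    ``u = t / (years * season_length)`` in [0, 1), so they are stated in data
    units regardless of series length.  ``seasonal_profile`` (length
    ``season_length``, mean zero) defaults to the weekly sinusoid above.
    """

    years: int = 15
    season_length: int = 62
    trend_coeffs: tuple = (25.0, 3.0, -2.0)
    seasonal_profile: np.ndarray | None = None
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.years < 0 or self.season_length < 1:
            raise ValueError("years must be >= 0 and season_length >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.seasonal_profile is not None:
            prof = np.asarray(self.seasonal_profile, dtype=float)
            if prof.size != self.season_length:
                raise ValueError("seasonal_profile must have season_length entries")
            if abs(prof.mean()) > 1e-9:
                raise ValueError("seasonal_profile must be mean-zero")
            object.__setattr__(self, "seasonal_profile", prof)

    def profile(self) -> np.ndarray:
        if self.seasonal_profile is not None:
            return self.seasonal_profile
        return default_weekly_profile(self.season_length)


def generate_series(cfg: SimConfig) -> tuple[TimeSeries, dict]:
    """Generate a series ``y = trend + seasonal + noise`` plus ground truth.

    Day identifiers are the progressive indices of the concatenated yearly
    windows; with ``missing_rate`` > 0 rows are dropped independently, so
    gaps are absent identifiers.  Identical config (including seed) yields
    identical output.

    Returns
    -------
    (series, truth)
        ``truth`` holds per-kept-row ``trend``, ``seasonal`` and ``noise``
        vectors, the full profile, and a config snapshot (RNG pinned by
        name) sufficient to regenerate the series.
    """
    n_slots = cfg.years * cfg.season_length
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n_slots)
    u = t / n_slots if n_slots else t.astype(float)
    trend = np.polynomial.polynomial.polyval(u, np.asarray(cfg.trend_coeffs, float))
    profile = cfg.profile()
    seasonal = profile[day_of_season(t, cfg.season_length) - 1] if n_slots else np.empty(0)
    noise = rng.normal(0.0, cfg.noise_sd, size=n_slots)
    keep = rng.random(n_slots) >= cfg.missing_rate if n_slots else np.empty(0, bool)
    y = trend + seasonal + noise
    series = TimeSeries(t=t[keep], y=y[keep])
    truth = {
        "trend": trend[keep],
        "seasonal": seasonal[keep],
        "noise": noise[keep],
        "profile": profile,
        "n_slots": int(n_slots),
        "config": {
            "years": cfg.years,
            "season_length": cfg.season_length,
            "trend_coeffs": list(cfg.trend_coeffs),
            "noise_sd": cfg.noise_sd,
            "missing_rate": cfg.missing_rate,
            "seed": cfg.seed,
            "rng": _RNG_NAME,
        },
    }
    return series, truth


def generate_weather(cfg: SimConfig) -> "pd.DataFrame":
    """Daily (Tmax, RH) rows for exercising the heat-index stage end to end.

    Tmax follows a within-season sinusoid around a warm summer level plus
    noise, clipped to the plausible [15, 45] degC; RH is uniform on
    [20, 95]%.  Seeded and reproducible like :func:`generate_series`.
    """
    import pandas as pd

    n_slots = cfg.years * cfg.season_length
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n_slots)
    d = day_of_season(t, cfg.season_length) if n_slots else np.empty(0)
    tmax = (
        30.0
        + 4.0 * np.sin(2.0 * np.pi * (np.asarray(d, float) - 1) / cfg.season_length)
        + rng.normal(0.0, 1.5, size=n_slots)
    )
    tmax = np.clip(tmax, 15.0, 45.0)
    rh = rng.uniform(20.0, 95.0, size=n_slots)
    return pd.DataFrame({"t": t, "tmax_c": tmax, "rh_pct": rh})
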