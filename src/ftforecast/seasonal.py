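"""Seasonal forecasting with first-order fuzzy transforms.

The forecaster decomposes a seasonal daily series additively into a slow
polynomial trend and a within-season fluctuation that repeats across years:

1. fit a least-squares polynomial trend on the progressive day axis
   (affinely mapped to [-1, 1] for conditioning);
2. subtract it, giving the de-trended fluctuation;
3. pool the de-trended observations by *day-of-season phase* (position
   1..season_length within the yearly window) and split the phase axis into
   S contiguous blocks ("seasons" — weekly blocks in the intended use);
4. per block, fit first-order fuzzy-transform components on an h-uniform
   raised-cosine partition of the block's phase window, growing the node
   count adaptively from 3 until the MAD-MEAN fit statistic drops to the
   threshold or the sample stops being sufficiently dense;
5. forecast any future day as trend(t) plus the block's inverse
   first-order transform evaluated at that day's phase.

Because the seasonal term is a function of phase only, two days in the same
phase of different years differ exactly by their trend difference, and
future years are forecastable without extrapolating the seasonal fit.

Time is carried as a *progressive day identifier*: the 0-based index of a
day within the concatenated yearly windows (62 slots per year for a
July-August window), so phase is simply ``t mod season_length + 1`` and gaps
are absent rows, never shifted indices.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ftransform import F1Components, f1_components, inverse_f1_transform
from .metrics import mad_mean_index
from .partition import (
    FuzzyPartition,
    build_uniform_partition,
    is_sufficiently_dense,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "TrendModel",
    "SeasonFit",
    "TSSF1Model",
    "day_of_season",
    "assign_seasons",
    "fit_trend",
    "eval_trend",
    "detrend",
    "fit_season",
    "fit_tssf1",
    "predict",
    "forecast_range",
    "save_model",
    "load_model",
]

# stop reasons recorded by the adaptive node search
STOP_THRESHOLD = "threshold_met"
STOP_DENSITY = "density_limit"
STOP_DEGENERATE = "degenerate"
STOP_NMAX = "n_max_reached"


@dataclass(frozen=True)
class TimeSeries:
    """A univariate series on the progressive-day axis.

    ``t`` holds strictly increasing integer day identifiers (missing days are
    simply absent); ``y`` the observed values.
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("t and y must be 1-d vectors of equal length")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("time indices must be strictly increasing")
        if not np.isfinite(y).all():
            raise ValueError("series values must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class TrendModel:
    """Polynomial trend on an affinely rescaled time axis.

    ``coef`` are power-series coefficients in the mapped variable; ``domain``
    is the (t_min, t_max) window mapped onto [-1, 1].  The mapping keeps a
    high-degree fit on day identifiers in the hundreds numerically sane.
    """

    degree: int
    coef: np.ndarray
    domain: tuple[float, float]

    def _poly(self) -> np.polynomial.Polynomial:
        return np.polynomial.Polynomial(self.coef, domain=list(self.domain))

    def __call__(self, t):
        return eval_trend(self, t)


def fit_trend(series: TimeSeries, degree: int = 9) -> TrendModel:
    """Least-squares polynomial trend of the given degree.

    Requires more observations than coefficients.  A rank-deficient design
    (e.g. nearly coincident times) is fitted anyway with a logged warning —
    numpy zeroes the unresolvable directions, reducing the effective degree.
    """
    degree = int(degree)
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    if len(series) <= degree:
        raise ValueError(
            f"need more than degree={degree} observations to fit a trend, "
            f"got {len(series)}"
        )
    t = np.asarray(series.t, dtype=float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", np.exceptions.RankWarning)
        poly = np.polynomial.Polynomial.fit(t, series.y, deg=degree)
        if any(issubclass(w.category, np.exceptions.RankWarning) for w in caught):
            logger.warning(
                "trend fit of degree %d is rank deficient; effective degree reduced",
                degree,
            )
    return TrendModel(
        degree=degree,
        coef=np.asarray(poly.coef, dtype=float),
        domain=(float(poly.domain[0]), float(poly.domain[1])),
    )


def eval_trend(model: TrendModel, t):
    """Evaluate the trend polynomial at ``t`` (extrapolation permitted)."""
    out = model._poly()(np.asarray(t, dtype=float))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def detrend(series: TimeSeries, model: TrendModel) -> TimeSeries:
    """Subtract the fitted trend elementwise."""
    return TimeSeries(t=series.t, y=series.y - eval_trend(model, series.t))


def day_of_season(t, season_length: int):
    """Phase 1..season_length of each progressive day identifier."""
    t = np.asarray(t)
    return t % season_length + 1


def assign_seasons(d, n_seasons: int, season_length: int):
    """Map day-of-season phases onto S contiguous blocks.

    Blocks have width ``ceil(season_length / S)``; the final block absorbs
    the remainder (e.g. 62 days in 9 blocks: eight of 7 days and one of 6).

    Raises
    ------
    ValueError
        For phases outside ``1..season_length`` or invalid S.
    """
    n_seasons = int(n_seasons)
    season_length = int(season_length)
    if n_seasons < 1 or season_length < n_seasons:
        raise ValueError(
            f"need 1 <= S <= season_length, got S={n_seasons}, "
            f"season_length={season_length}"
        )
    d = np.asarray(d)
    if ((d < 1) | (d > season_length)).any():
        raise ValueError(f"day-of-season out of range 1..{season_length}")
    block = -(-season_length // n_seasons)  # ceil division
    s = np.minimum((d + block - 1) // block, n_seasons)
    return s


@dataclass(frozen=True)
class SeasonFit:
    """One seasonal block: its phase window, partition and fitted components.

    ``history`` records (node count, MAD-MEAN) for every completed iteration
    of the adaptive search; the stored fit is the accepted iteration.  A
    degenerate block (too few distinct phases for even a 3-node partition)
    carries only its constant fallback.
    """

    season: int
    phase_lo: float
    phase_hi: float
    n_nodes: int
    partition: FuzzyPartition | None
    components: F1Components | None
    constant: float
    mad_mean: float
    stop_reason: str
    history: tuple = field(default_factory=tuple)

    def seasonal_value(self, d):
        """Seasonal term at phase(s) ``d``, clamped to the fitted window."""
        if self.partition is None or self.components is None:
            out = np.full(np.shape(np.atleast_1d(d)), self.constant)
        else:
            d_arr = np.clip(
                np.asarray(d, dtype=float), self.phase_lo, self.phase_hi
            )
            out = np.atleast_1d(
                inverse_f1_transform(self.partition, self.components, d_arr)
            )
        if np.isscalar(d) or np.ndim(d) == 0:
            return float(out[0])
        return out


def fit_season(
    phases,
    values,
    raw_values,
    threshold: float,
    *,
    season: int = 0,
    n_min: int = 3,
    n_max: int | None = None,
) -> SeasonFit:
    """Adaptive node search for one seasonal block.

    Starting from ``n_min`` (3) nodes on the block's observed phase window,
    grow the partition one node at a time.  Each iteration fits first-order
    components to the de-trended ``values`` and scores the fit with
    MAD-MEAN — total absolute residual over the total of ``raw_values``
    (the raw series sets the scale; the trend cancels in the residual).
    The search accepts the first node count whose MAD-MEAN reaches the
    threshold; if the sample stops being sufficiently dense first, the last
    dense fit is returned; if even 3 nodes are infeasible (fewer than 3
    distinct phases, or a non-dense initial partition), a constant fallback
    at the subset mean is returned.

    The search always terminates: the node spacing shrinks toward zero while
    the phase set is finite, so density must eventually fail, and ``n_max``
    (default: the number of distinct phases) bounds the work before that.
    """
    phases = np.asarray(phases, dtype=float)
    values = np.asarray(values, dtype=float)
    raw_values = np.asarray(raw_values, dtype=float)
    if phases.size == 0:
        raise ValueError("cannot fit an empty seasonal subset")
    if not (phases.size == values.size == raw_values.size):
        raise ValueError("phases, values and raw_values must have equal length")
    if not threshold > 0:
        raise ValueError("threshold must be positive")

    distinct = np.unique(phases)
    lo, hi = float(distinct[0]), float(distinct[-1])

    def _degenerate() -> SeasonFit:
        return SeasonFit(
            season=season,
            phase_lo=lo,
            phase_hi=hi,
            n_nodes=1,
            partition=None,
            components=None,
            constant=float(values.mean()),
            mad_mean=_score(np.full_like(values, values.mean())),
            stop_reason=STOP_DEGENERATE,
        )

    def _score(fitted) -> float:
        mm = mad_mean_index(fitted - values, raw_values)
        return float("inf") if mm is None else mm

    if distinct.size < 3 or hi <= lo:
        return _degenerate()

    if n_max is None:
        n_max = max(int(n_min), int(distinct.size))

    history: list[tuple[int, float]] = []
    accepted: tuple[int, FuzzyPartition, F1Components, float] | None = None
    stop_reason = STOP_NMAX
    for n in range(int(n_min), int(n_max) + 1):
        part = build_uniform_partition(lo, hi, n)
        dense, _ = is_sufficiently_dense(part, phases)
        if not dense:
            if accepted is None:
                return _degenerate()
            stop_reason = STOP_DENSITY
            break
        comps = f1_components(part, phases, values)
        mm = _score(inverse_f1_transform(part, comps, phases))
        history.append((n, mm))
        accepted = (n, part, comps, mm)
        if mm <= threshold:
            stop_reason = STOP_THRESHOLD
            break

    assert accepted is not None
    n, part, comps, mm = accepted
    return SeasonFit(
        season=season,
        phase_lo=lo,
        phase_hi=hi,
        n_nodes=n,
        partition=part,
        components=comps,
        constant=0.0,
        mad_mean=mm,
        stop_reason=stop_reason,
        history=tuple(history),
    )


@dataclass(frozen=True)
class TSSF1Model:
    """The full fitted forecaster: trend plus S seasonal block fits."""

    trend: TrendModel
    seasons: tuple[SeasonFit, ...]
    n_seasons: int
    season_length: int
    config: dict

    def to_dict(self) -> dict:
        return {
            "trend": {
                "degree": self.trend.degree,
                "coef": list(self.trend.coef),
                "domain": list(self.trend.domain),
            },
            "n_seasons": self.n_seasons,
            "season_length": self.season_length,
            "config": self.config,
            "seasons": [
                {
                    "season": sf.season,
                    "phase_lo": sf.phase_lo,
                    "phase_hi": sf.phase_hi,
                    "n_nodes": sf.n_nodes,
                    "c0": list(sf.components.c0) if sf.components else None,
                    "c1": list(sf.components.c1) if sf.components else None,
                    "constant": sf.constant,
                    "mad_mean": sf.mad_mean,
                    "stop_reason": sf.stop_reason,
                    "history": [list(h) for h in sf.history],
                }
                for sf in self.seasons
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TSSF1Model":
        trend = TrendModel(
            degree=int(data["trend"]["degree"]),
            coef=np.asarray(data["trend"]["coef"], dtype=float),
            domain=tuple(data["trend"]["domain"]),
        )
        seasons = []
        for sd in data["seasons"]:
            if sd["c0"] is not None:
                part = build_uniform_partition(
                    sd["phase_lo"], sd["phase_hi"], sd["n_nodes"]
                )
                comps = F1Components(
                    c0=np.asarray(sd["c0"], dtype=float),
                    c1=np.asarray(sd["c1"], dtype=float),
                )
            else:
                part, comps = None, None
            seasons.append(
                SeasonFit(
                    season=int(sd["season"]),
                    phase_lo=float(sd["phase_lo"]),
                    phase_hi=float(sd["phase_hi"]),
                    n_nodes=int(sd["n_nodes"]),
                    partition=part,
                    components=comps,
                    constant=float(sd["constant"]),
                    mad_mean=float(sd["mad_mean"]),
                    stop_reason=sd["stop_reason"],
                    history=tuple(tuple(h) for h in sd.get("history", [])),
                )
            )
        return cls(
            trend=trend,
            seasons=tuple(seasons),
            n_seasons=int(data["n_seasons"]),
            season_length=int(data["season_length"]),
            config=dict(data.get("config", {})),
        )


def fit_tssf1(
    series: TimeSeries,
    *,
    degree: int = 9,
    n_seasons: int = 9,
    season_length: int = 62,
    threshold: float = 5.0,
    n_min: int = 3,
    n_max: int | None = None,
) -> TSSF1Model:
    """Fit the full seasonal forecaster.

    Composes trend fit, de-trending, phase-block assignment and the
    per-block adaptive node search.  A block with no observations at all is
    recorded as a degenerate zero-constant fit with a logged warning.
    """
    span = int(series.t[-1]) - int(series.t[0]) + 1
    if span < season_length:
        raise ValueError("series must span at least one full season")
    trend = fit_trend(series, degree)
    resid = detrend(series, trend)
    d = day_of_season(series.t, season_length)
    s = assign_seasons(d, n_seasons, season_length)

    fits: list[SeasonFit] = []
    block = -(-season_length // n_seasons)
    for season in range(1, n_seasons + 1):
        mask = s == season
        if not mask.any():
            logger.warning("season %d has no observations; constant-0 fallback", season)
            lo = (season - 1) * block + 1
            hi = min(season * block, season_length)
            fits.append(
                SeasonFit(
                    season=season,
                    phase_lo=float(lo),
                    phase_hi=float(hi),
                    n_nodes=1,
                    partition=None,
                    components=None,
                    constant=0.0,
                    mad_mean=float("inf"),
                    stop_reason=STOP_DEGENERATE,
                )
            )
            continue
        fit = fit_season(
            d[mask].astype(float),
            resid.y[mask],
            series.y[mask],
            threshold,
            season=season,
            n_min=n_min,
            n_max=n_max,
        )
        logger.info(
            "season %d: n=%d MAD-MEAN=%.4g stop=%s",
            season,
            fit.n_nodes,
            fit.mad_mean,
            fit.stop_reason,
        )
        fits.append(fit)
    return TSSF1Model(
        trend=trend,
        seasons=tuple(fits),
        n_seasons=n_seasons,
        season_length=season_length,
        config={
            "degree": degree,
            "n_seasons": n_seasons,
            "season_length": season_length,
            "threshold": threshold,
            "n_min": n_min,
            "n_max": n_max,
        },
    )


def predict(model: TSSF1Model, t):
    """Forecast at progressive day identifier(s) ``t``.

    The prediction is trend(t) plus the seasonal term of t's phase block;
    the seasonal term depends on the day-of-season phase only.
    """
    t_arr = np.atleast_1d(np.asarray(t))
    d = day_of_season(t_arr, model.season_length)
    s = assign_seasons(d, model.n_seasons, model.season_length)
    out = np.asarray(eval_trend(model.trend, t_arr), dtype=float).copy()
    for season in np.unique(s):
        mask = s == season
        out[mask] += model.seasons[int(season) - 1].seasonal_value(
            d[mask].astype(float)
        )
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def forecast_range(model: TSSF1Model, t_start: int, t_end: int) -> TimeSeries:
    """Vectorized :func:`predict` over the half-open range [t_start, t_end)."""
    t = np.arange(int(t_start), int(t_end))
    if t.size == 0:
        return TimeSeries(t=t, y=np.empty(0))
    return TimeSeries(t=t, y=predict(model, t))


def save_model(model: TSSF1Model, path) -> None:
    """Write the model as a JSON document (reloads bit-identically)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> TSSF1Model:
    return TSSF1Model.from_dict(json.loads(Path(path).read_text()))
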