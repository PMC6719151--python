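"""CSV / JSON / YAML input-output and run configuration.

File formats (all plain text, fixed column names):

* series CSV: header ``t,value`` (integer progressive day identifiers) or
  ``date,value`` (ISO-8601 dates inside the yearly seasonal windows);
* weather CSV: ``date,tmax_c,rh_pct`` or ``t,tmax_c,rh_pct``;
* model JSON: the serialized forecaster (see :mod:`ftforecast.seasonal`);
* config YAML/JSON: any subset of the :class:`RunConfig` fields.

Dates are mapped onto the *progressive identifier* axis: day ``k`` (0-based)
of the seasonal window of year ``j`` (counted from the first year present)
gets identifier ``j * season_length + k``.  This keeps the trend fit
conditioned and makes phase arithmetic trivial; dates outside the seasonal
window are rejected (or skipped where the caller asks for that).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .seasonal import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "progressive_ids_from_dates",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the standard defaults.

    Defaults: 9th-degree trend, 9 weekly seasonal blocks over a 62-day
    window (July-August), MAD-MEAN stopping threshold 5 (percent), node
    search starting at 3.
    """

    degree: int = 9
    n_seasons: int = 9
    season_length: int = 62
    threshold: float = 5.0
    n_min: int = 3
    n_max: int | None = None
    window_start: str = "07-01"  # MM-DD of the first day of each window
    seed: int = 0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_min < 3:
            raise ValueError("n_min must be at least 3")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _window_start(year: int, window_start: str) -> _dt.date:
    month, day = (int(p) for p in window_start.split("-"))
    return _dt.date(year, month, day)


def progressive_ids_from_dates(
    dates,
    season_length: int = 62,
    window_start: str = "07-01",
    base_year: int | None = None,
) -> np.ndarray:
    """Map ISO dates inside yearly seasonal windows to progressive day ids.

    Raises
    ------
    ValueError
        For a date outside its year's seasonal window.
    """
    dates = [
        d.date() if isinstance(d, _dt.datetime) else
        (d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d)))
        for d in np.asarray(dates).tolist()
    ]
    if not dates:
        return np.empty(0, dtype=int)
    if base_year is None:
        base_year = min(d.year for d in dates)
    ids = []
    for d in dates:
        offset = (d - _window_start(d.year, window_start)).days
        if not 0 <= offset < season_length:
            raise ValueError(
                f"date {d.isoformat()} outside the {season_length}-day "
                f"window starting {window_start}"
            )
        ids.append((d.year - base_year) * season_length + offset)
    return np.asarray(ids, dtype=int)


def read_timeseries_csv(
    path,
    season_length: int = 62,
    window_start: str = "07-01",
) -> TimeSeries:
    """Read a series CSV with columns ``t,value`` or ``date,value``.

    Out-of-order rows are sorted with a warning; duplicate time stamps are
    an error.  Unparseable rows are reported with their line number.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = list(frame.columns)
    if "value" not in cols or not ({"t", "date"} & set(cols)):
        raise ValueError(
            f"{path}: expected columns (t|date, value), got {cols}"
        )
    if "t" in cols:
        try:
            t = frame["t"].to_numpy(dtype=int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-integer day identifiers: {exc}") from exc
    else:
        bad = frame.index[frame["date"].isna()]
        if len(bad):
            raise ValueError(f"{path}: unparseable date at line {bad[0] + 2}")
        t = progressive_ids_from_dates(
            frame["date"], season_length=season_length, window_start=window_start
        )
    values = frame["value"].to_numpy(dtype=float)
    if pd.isna(values).any():
        line = int(np.flatnonzero(pd.isna(values))[0]) + 2
        raise ValueError(f"{path}: missing/unparseable value at line {line}")
    order = np.argsort(t, kind="stable")
    if not (order == np.arange(len(order))).all():
        logger.warning("%s: rows out of time order; sorting", path)
        t, values = t[order], values[order]
    if len(t) > 1 and (np.diff(t) == 0).any():
        dup = int(t[np.flatnonzero(np.diff(t) == 0)[0]])
        raise ValueError(f"{path}: duplicate time stamp (t={dup})")
    return TimeSeries(t=t, y=values)


def write_timeseries_csv(series: TimeSeries, path) -> None:
    """Write a series as a ``t,value`` CSV (round-trips through the reader)."""
    frame = pd.DataFrame({"t": series.t, "value": series.y})
    # %.17g guarantees binary round-trip through the text format
    frame.to_csv(path, index=False, float_format="%.17g")
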