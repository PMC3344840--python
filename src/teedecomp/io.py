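"""Readers and writers for metabolic-chamber data.

Supports CLAMS-style CSV exports (time stamps, VO2/VCO2 or a precomputed
TEE column, and X/Z infrared beam-break totals) as well as the package's
own two-file tidy format (``tee.csv`` + ``pa.csv``) used by the simulator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalorimetryDataset",
    "ChamberLayout",
    "lusk_tee",
    "read_chamber_csv",
    "read_dataset",
    "write_dataset",
]

_HOURS_PER_DAY = 24.0


@dataclass
class CalorimetryDataset:
    """Paired TEE and activity traces on their own uniform time grids.

    Attributes
    ----------
    t_y, y
        TEE sample times (seconds from experiment start) and TEE (kcal/day).
    t_x, x
        Activity sample times (s) and beam-break counts per interval.
    meta
        Free-form metadata (animal id, light-cycle onset hour, units...).
    """

    t_y: np.ndarray
    y: np.ndarray
    t_x: np.ndarray
    x: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_y = np.asarray(self.t_y, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t_y.shape != self.y.shape or self.t_x.shape != self.x.shape:
            raise ValueError("time grids and traces must have matching shapes")
        for t, name in ((self.t_y, "t_y"), (self.t_x, "t_x")):
            if t.size >= 2 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if np.any(self.x[np.isfinite(self.x)] < 0):
            raise ValueError("activity counts must be non-negative")
        if np.any(self.y[np.isfinite(self.y)] <= 0):
            warnings.warn("non-positive TEE values present", stacklevel=2)

    @property
    def dt_tee(self) -> float:
        return float(np.median(np.diff(self.t_y)))

    @property
    def dt_pa(self) -> float:
        return float(np.median(np.diff(self.t_x)))

    @property
    def span_days(self) -> float:
        return float(self.t_y[-1] - self.t_y[0]) / 86400.0


def lusk_tee(vo2, vco2):
    """Caloric equivalent of gas exchange after Lusk's table.

    TEE [kcal/day] = (3.815 + 1.232 * RER) [kcal/l O2] * VO2 [l/h] * 24,
    with RER = VCO2/VO2.  Inputs are array-like in litres per hour.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 <= 0):
        raise ValueError("VO2 must be strictly positive")
    rer = vco2 / vo2
    if np.any((rer < 0.6) | (rer > 1.3)):
        raise ValueError("RER outside the physiological range [0.6, 1.3]")
    if np.any((rer < 0.7) | (rer > 1.0)):
        warnings.warn("RER outside the usual range [0.7, 1.0]", stacklevel=2)
    kcal_per_l = 3.815 + 1.232 * rer
    out = kcal_per_l * vo2 * _HOURS_PER_DAY
    return float(out) if out.ndim == 0 else out


@dataclass
class ChamberLayout:
    """Column mapping for a chamber CSV export.

    Either ``tee_col`` or the (``vo2_col``, ``vco2_col``) pair must be
    present in the file.  ``cumulative_counts=True`` handles exports that
    report running beam-break totals instead of per-interval counts.
    """

    time_col: str = "time"
    tee_col: str | None = "tee"
    vo2_col: str | None = None
    vco2_col: str | None = None
    x_col: str | None = "xtot"
    z_col: str | None = None
    cumulative_counts: bool = False
    gas_units_l_per_h: bool = True


def _parse_times(col: pd.Series) -> np.ndarray:
    """Timestamps or numeric seconds -> seconds from the first sample."""
    if np.issubdtype(col.dtype, np.number):
        t = col.to_numpy(dtype=float)
        return t - t[0]
    ts = pd.to_datetime(col)
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()


def _mask_gaps(t: np.ndarray, vals: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Re-grid onto the modal interval, NaN-masking missing samples.

    A single missing row is tolerated silently; longer irregularities
    raise, listing the offending positions.
    """
    d = np.diff(t)
    dt = float(np.median(d))
    if dt <= 0:
        raise ValueError(f"{what}: non-increasing time stamps")
    steps = np.rint(d / dt).astype(int)
    bad = np.flatnonzero(np.abs(d - steps * dt) > 0.01 * dt)
    if bad.size:
        raise ValueError(
            f"{what}: non-uniform sampling at rows {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    idx = np.concatenate([[0], np.cumsum(steps)])
    n = idx[-1] + 1
    full_t = t[0] + dt * np.arange(n)
    full_v = np.full(n, np.nan)
    full_v[idx] = vals
    return full_t, full_v


def read_chamber_csv(
    path: str | Path,
    layout: ChamberLayout | None = None,
    drop_first_hours: float = 0.0,
) -> CalorimetryDataset:
    """Parse a chamber CSV export into a :class:`CalorimetryDataset`.

    Activity is reported as total X+Z beam breaks per interval divided by
    the sample time in minutes (counts/min convention); TEE is taken from
    ``tee_col`` or computed from VO2/VCO2 via :func:`lusk_tee`.  The first
    ``drop_first_hours`` (acclimatisation) are discarded.
    """
    layout = layout or ChamberLayout()
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    need = [layout.time_col]
    if layout.tee_col and layout.tee_col in df.columns:
        tee_from_gas = False
    elif layout.vo2_col and layout.vco2_col:
        tee_from_gas = True
        need += [layout.vo2_col, layout.vco2_col]
    else:
        raise ValueError("layout must name a TEE column or VO2/VCO2 columns")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    t = _parse_times(df[layout.time_col])
    if tee_from_gas:
        tee = lusk_tee(df[layout.vo2_col].to_numpy(), df[layout.vco2_col].to_numpy())
    else:
        tee = df[layout.tee_col].to_numpy(dtype=float)

    counts = np.zeros(len(df))
    any_pa = False
    for col in (layout.x_col, layout.z_col):
        if col and col in df.columns:
            counts = counts + df[col].to_numpy(dtype=float)
            any_pa = True
    if not any_pa:
        raise ValueError("no activity (beam-break) columns found")
    if layout.cumulative_counts:
        counts = np.diff(counts, prepend=counts[0] - (counts[1] - counts[0]))
        counts = np.maximum(counts, 0.0)

    t_y, y = _mask_gaps(t, tee, "TEE")
    t_x, x = _mask_gaps(t, counts, "PA")
    dt_min = float(np.median(np.diff(t_x))) / 60.0
    pa_rate = x / dt_min  # counts per minute, CLAMS convention

    keep_y = t_y >= drop_first_hours * 3600.0
    keep_x = t_x >= drop_first_hours * 3600.0
    t0 = t_y[keep_y][0] if keep_y.any() else 0.0
    return CalorimetryDataset(
        t_y=t_y[keep_y] - t0,
        y=y[keep_y],
        t_x=t_x[keep_x] - t0,
        x=pa_rate[keep_x],
        meta={"source": str(path), "pa_units": "counts/min"},
    )


def write_dataset(ds: CalorimetryDataset, directory: str | Path) -> None:
    """Write ``tee.csv``, ``pa.csv`` and ``meta.json`` to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    # %.17g keeps doubles bit-exact through the text round trip
    pd.DataFrame({"time_s": ds.t_y, "tee_kcal_day": ds.y}).to_csv(
        d / "tee.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame({"time_s": ds.t_x, "counts": ds.x}).to_csv(
        d / "pa.csv", index=False, float_format="%.17g"
    )
    (d / "meta.json").write_text(json.dumps(ds.meta, indent=2, default=float))


def read_dataset(directory: str | Path) -> CalorimetryDataset:
    """Read the two-file tidy format written by :func:`write_dataset`."""
    d = Path(directory)
    tee = pd.read_csv(d / "tee.csv", float_precision="round_trip")
    pa = pd.read_csv(d / "pa.csv", float_precision="round_trip")
    meta = {}
    if (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
    return CalorimetryDataset(
        t_y=tee["time_s"].to_numpy(),
        y=tee["tee_kcal_day"].to_numpy(),
        t_x=pa["time_s"].to_numpy(),
        x=pa["counts"].to_numpy(),
        meta=meta,
    )
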