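"""Synthetic metabolic-chamber datasets with known ground truth.

A simulated mouse spends three days in a virtual chamber.  Its resting
metabolic rate is a 24 h cosine (peaking mid-dark, since mice are
nocturnal) plus a low-pass filtered Gaussian process for slower ultradian
drift, around a mean of 10 kcal/day.  Activity arrives as an alternating
renewal process of rectangular bouts -- exponential inter-bout gaps with
a higher rate at night, log-normal durations and intensities -- and each
bout carries its own caloric cost of activity drawn around the population
mean, so the PA-AEE link is only correct on average (the source of the
multiplicative activity error the estimator corrects for).  Beam-break
counts are an inhomogeneous Poisson read-out of the intensity on a 1 s
lattice, binned to the sample interval.  The observed TEE is the
instantaneous RMR + AEE pushed through the two-compartment chamber
washout filter, sampled, and corrupted with additive Gaussian noise.

Everything the chamber cannot see (instantaneous RMR, AEE, the bout
table, per-bout costs) is retained in :class:`SimTruth` as the accuracy
reference for the validation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt, fftconvolve

from .diffusion import DiffusionParams, impulse_response
from .io import CalorimetryDataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_rmr",
    "simulate_bouts",
    "simulate_dataset",
    "downsample",
    "downsample_dataset",
    "write_sim_dataset",
]

_SEC_PER_DAY = 86400.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (defaults emulate a mouse CLAMS recording).

    Times in the units stated; the light phase occupies the first
    ``light_hours`` of each simulated day (recording starts at light
    onset), the dark phase the remainder.
    """

    days: float = 3.0
    dt: float = 10.0                  # base sample interval, s
    # resting metabolic rate
    mean_rmr: float = 10.0            # kcal/day
    circadian_amp: float = 1.0        # peak-to-peak, kcal/day
    acrophase_h: float = 18.0         # hours after light onset (mid-dark)
    gp_sd: float = 0.45               # kcal/day, SD of the slow stochastic part
    gp_cutoff: float = 6.0            # cycles/day low-pass cutoff
    # activity bouts
    gap_day_min: float = 30.0         # mean inter-bout gap, light phase
    gap_night_min: float = 10.0       # mean inter-bout gap, dark phase
    bout_duration_min: float = 2.5    # mean bout duration (log-normal)
    bout_duration_cv: float = 0.8
    bout_intensity_mean: float = 4.0  # arbitrary intensity units
    bout_intensity_cv: float = 0.5
    # energetics of activity
    cca_mean: float = 2.0             # kcal/day per intensity unit
    cca_cv: float = 0.2               # between-bout variation of the cost
    # sensors
    beam_rate: float = 0.6            # expected beam breaks / s / intensity unit
    exact_pa: bool = False            # skip Poisson sampling (noise-free PA)
    noise_sd: float = 0.5             # additive TEE noise, kcal/day
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    apply_diffusion: bool = True
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.days <= 0 or self.dt <= 0:
            raise ValueError("days and dt must be positive")
        if abs((_SEC_PER_DAY / self.dt) % 1.0) > 1e-9:
            raise ValueError("dt must divide one day")
        for name in ("gp_sd", "noise_sd", "cca_cv", "bout_duration_cv",
                     "bout_intensity_cv", "beam_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_rmr - self.circadian_amp / 2.0 <= 0:
            raise ValueError("circadian amplitude drives RMR non-positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.days * _SEC_PER_DAY / self.dt))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["diffusion"] = self.diffusion.to_dict()
        return d


@dataclass
class SimTruth:
    """Ground truth on the base sample grid (instantaneous, pre-sensor)."""

    t: np.ndarray
    rmr: np.ndarray
    aee: np.ndarray
    intensity: np.ndarray
    bouts: pd.DataFrame
    config: SimConfig

    @property
    def mean_rmr(self) -> float:
        return float(np.mean(self.rmr))


@dataclass
class SimDataset:
    observed: CalorimetryDataset
    truth: SimTruth
    seed: int | None = None


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and CV."""
    s2 = np.log(1.0 + cv**2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def simulate_rmr(config: SimConfig, rng: np.random.Generator,
                 t: np.ndarray | None = None) -> np.ndarray:
    """Cosine day-night rhythm plus low-pass filtered Gaussian drift.

    The stochastic part is generated as white noise on a 60 s lattice,
    low-pass filtered at ``gp_cutoff`` cycles/day, scaled to an exact
    ensemble SD of ``gp_sd`` via the filter's noise gain, and
    interpolated to the requested grid.  Values are floored just above
    zero (a physiological RMR cannot be negative); the floor is inactive
    for any sane parameter choice.
    """
    if t is None:
        t = np.arange(config.n_samples) * config.dt
    th = t / 3600.0
    rmr = config.mean_rmr + (config.circadian_amp / 2.0) * np.cos(
        2.0 * np.pi * (th - config.acrophase_h) / 24.0
    )
    if config.gp_sd > 0:
        dt_gp = 60.0
        n_gp = int(np.ceil((t[-1] + dt_gp) / dt_gp)) + 1
        nyq = 0.5 * _SEC_PER_DAY / dt_gp          # cycles/day
        sos = butter(2, config.gp_cutoff / nyq, output="sos")
        gain = np.sqrt(np.sum(sosfilt(sos, np.eye(1, n_gp, 0)[0]) ** 2))
        noise = sosfilt(sos, rng.standard_normal(n_gp)) * (config.gp_sd / gain)
        rmr = rmr + np.interp(t, np.arange(n_gp) * dt_gp, noise)
    return np.maximum(rmr, 1e-6)


def simulate_bouts(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Alternating-renewal activity bouts rastered on a 1 s lattice.

    Returns the intensity trace (1 s resolution, length days*86400) and a
    bout table with columns start_s, duration_s, intensity, cca.
    """
    n1 = int(round(config.days * _SEC_PER_DAY))
    intensity = np.zeros(n1)
    mu_d, sd_d = _lognormal_params(config.bout_duration_min * 60.0,
                                   config.bout_duration_cv)
    mu_i, sd_i = _lognormal_params(config.bout_intensity_mean,
                                   config.bout_intensity_cv)
    mu_c, sd_c = _lognormal_params(config.cca_mean, config.cca_cv)
    rows = []
    t = 0.0
    light_s = config.light_hours * 3600.0
    while True:
        in_light = (t % _SEC_PER_DAY) < light_s
        gap_mean = (config.gap_day_min if in_light else config.gap_night_min) * 60.0
        if not np.isfinite(gap_mean) or gap_mean <= 0:
            break
        t += rng.exponential(gap_mean)
        if t >= n1:
            break
        dur = rng.lognormal(mu_d, sd_d)
        inten = rng.lognormal(mu_i, sd_i)
        cca = rng.lognormal(mu_c, sd_c) if config.cca_cv > 0 else config.cca_mean
        i0 = int(t)
        i1 = min(int(np.ceil(t + dur)), n1)
        intensity[i0:i1] += inten
        rows.append((t, dur, inten, cca))
        t += dur
    bouts = pd.DataFrame(rows, columns=["start_s", "duration_s", "intensity", "cca"])
    return intensity, bouts


def _zero_bout_config(config: SimConfig) -> bool:
    return (np.isinf(config.gap_day_min) and np.isinf(config.gap_night_min))


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimDataset:
    """Generate one chamber recording plus its ground truth.

    Deterministic given ``seed``; the observed TEE equals
    ``washout_filter(RMR + AEE)`` sampled at the base interval plus
    i.i.d. Gaussian noise, and the beam-break counts are Poisson draws on
    a 1 s lattice binned into the same intervals.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    dt = int(round(config.dt))
    n1 = n * dt
    t1 = np.arange(n1, dtype=float)                 # 1 s lattice
    t = np.arange(n, dtype=float) * config.dt       # base grid

    rmr1 = simulate_rmr(config, rng, t1)

    if _zero_bout_config(config):
        intensity1 = np.zeros(n1)
        bouts = pd.DataFrame(columns=["start_s", "duration_s", "intensity", "cca"])
        aee1 = np.zeros(n1)
    else:
        intensity1, bouts = simulate_bouts(config, rng)
        # per-second caloric cost: bouts may overlap, use intensity-weighted cost
        cost1 = np.full(n1, config.cca_mean)
        weight = np.zeros(n1)
        num = np.zeros(n1)
        for row in bouts.itertuples(index=False):
            i0, i1 = int(row.start_s), min(int(np.ceil(row.start_s + row.duration_s)), n1)
            num[i0:i1] += row.intensity * row.cca
            weight[i0:i1] += row.intensity
        act = weight > 0
        cost1[act] = num[act] / weight[act]
        aee1 = intensity1 * cost1

    tee_inst1 = rmr1 + aee1
    if config.apply_diffusion:
        _, h = impulse_response(config.diffusion, 1.0)
        # warm start: the animal was already resting in the chamber before
        # recording began, so pre-history is the initial RMR (no activity)
        pad = np.full(h.size, rmr1[0])
        tee_sensor1 = fftconvolve(np.concatenate([pad, tee_inst1]), h * 1.0)[
            h.size: h.size + n1
        ]
    else:
        tee_sensor1 = tee_inst1
    idx = (np.arange(n) * dt).astype(int)
    y = tee_sensor1[idx]
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)

    # beam-break read-out: Poisson on the 1 s lattice, binned per interval
    lam = config.beam_rate * intensity1
    breaks1 = lam if config.exact_pa else rng.poisson(lam)
    counts = breaks1.reshape(n, dt).sum(axis=1).astype(float)

    observed = CalorimetryDataset(
        t_y=t, y=y, t_x=t.copy(), x=counts,
        meta={"simulated": True, "seed": seed, "dt_s": config.dt,
              "light_hours": config.light_hours},
    )
    truth = SimTruth(
        t=t,
        rmr=rmr1[idx],
        aee=aee1.reshape(n, dt).mean(axis=1),
        intensity=intensity1.reshape(n, dt).mean(axis=1),
        bouts=bouts,
        config=config,
    )
    return SimDataset(observed=observed, truth=truth, seed=seed)


def downsample(trace: np.ndarray, N: int, mode: str = "decimate",
               offset: int = 0) -> np.ndarray:
    """Emulate a lower sample rate.

    ``decimate`` keeps every N-th value (the TEE convention: gas analysers
    report instantaneous readings); ``bin_sum`` sums blocks of N (the PA
    convention: beam breaks accumulate over the reporting interval).
    ``offset`` in 0..N-1 selects the phase of the kept samples.
    """
    trace = np.asarray(trace)
    if N < 1 or int(N) != N:
        raise ValueError("N must be a positive integer")
    N = int(N)
    if N > trace.size:
        raise ValueError("N longer than the trace")
    if not 0 <= offset < N:
        raise ValueError("offset must be in 0..N-1")
    if mode == "decimate":
        return trace[offset::N]
    if mode == "bin_sum":
        m = (trace.size - offset) // N
        return trace[offset: offset + m * N].reshape(m, N).sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def downsample_dataset(
    sim: SimDataset, N_tee: int, N_pa: int | None = None, offset: int = 0
) -> tuple[CalorimetryDataset, np.ndarray, np.ndarray]:
    """Down-rate a simulated recording; returns (dataset, t_kept, truth_rmr).

    TEE is decimated (phase ``offset``); PA is block-summed over the same
    windows when ``N_pa`` is given, or kept at the base rate when
    ``N_pa`` is None / 1 (the high-rate-PA regime).  ``truth_rmr`` is the
    instantaneous truth at the kept TEE instants.
    """
    obs, truth = sim.observed, sim.truth
    t_y = downsample(obs.t_y, N_tee, "decimate", offset)
    y = downsample(obs.y, N_tee, "decimate", offset)
    if N_pa is None or N_pa == 1:
        t_x, x = obs.t_x, obs.x
    else:
        x = downsample(obs.x, N_pa, "bin_sum", offset)
        t_x = obs.t_x[offset + N_pa - 1:: N_pa][: x.size]
    ds = CalorimetryDataset(t_y=t_y, y=y, t_x=t_x, x=x, meta=dict(obs.meta))
    return ds, t_y, downsample(truth.rmr, N_tee, "decimate", offset)


def write_sim_dataset(sim: SimDataset, directory: str | Path) -> None:
    """Write tee.csv, pa.csv, truth.csv and config.json."""
    from .io import write_dataset

    d = Path(directory)
    write_dataset(sim.observed, d)
    pd.DataFrame(
        {
            "time_s": sim.truth.t,
            "rmr_kcal_day": sim.truth.rmr,
            "aee_kcal_day": sim.truth.aee,
            "intensity": sim.truth.intensity,
        }
    ).to_csv(d / "truth.csv", index=False)
    (d / "config.json").write_text(
        json.dumps(sim.truth.config.to_dict(), indent=2, default=float)
    )
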