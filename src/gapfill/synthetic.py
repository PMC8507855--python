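"""Synthetic temperature-like series with the structure the imputers assume.

Real station data of this kind (half-hourly machine records plus manual
thermometer readings three times a day) is rarely redistributable, so every
experiment in this package runs on simulated series that reproduce the
relevant statistical features: an annual sinusoidal cycle, a diurnal
sinusoidal cycle, slowly decaying autocorrelated weather deviations (a
shared AR(1) process at the half-hour step), white measurement noise on the
machine channel, and manual readings related to the truth by a small affine
offset plus noise.

What this generator does *not* emulate — weather fronts, rain events,
asymmetric diurnal shapes — is documented in docs/methods.md; conclusions
drawn from it concern the imputation machinery, not meteorology.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .series import GapSpec, RegularSeries, DEFAULT_ANCHOR_SLOTS

DEFAULT_START = pd.Timestamp("2019-01-01 00:00")


@dataclass(frozen=True)
class WeatherConfig:
    """Generator parameters (temperatures in °C).

    Defaults are tuned to a humid subtropical site: warm mean, moderate
    seasonal swing, a ~4 °C half-amplitude diurnal cycle peaking mid
    afternoon, and weather deviations that decorrelate over several hours.
    """

    mean_temp: float = 22.0
    annual_amplitude: float = 6.0
    diurnal_amplitude: float = 4.0
    diurnal_phase: int = 17          # slots; sin peaks 12 slots later (14:30)
    ar1_phi: float = 0.95
    ar1_sd: float = 0.6
    obs_noise_sd: float = 0.2
    manual_bias: float = 0.3
    manual_noise_sd: float = 0.2
    n_days: int = 730
    seed: int = 0

    def __post_init__(self):
        if not abs(self.ar1_phi) < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if min(self.ar1_sd, self.obs_noise_sd, self.manual_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_temperature(cfg: WeatherConfig,
                         start_time: pd.Timestamp = DEFAULT_START
                         ) -> tuple[RegularSeries, RegularSeries]:
    """Simulate (truth, machine) half-hourly series of ``cfg.n_days`` days.

    truth(t) = mean + A_annual·sin(2π·day/365.25)
                    + A_diurnal·sin(2π·(slot − phase)/48)
                    + AR(1) deviation (shared across slots, stationary init)
    machine(t) = truth(t) + iid N(0, obs_noise_sd²).
    """
    rng = np.random.default_rng(cfg.seed)
    spd = 48
    L = cfg.n_days * spd
    t = np.arange(L)
    day = t / spd
    slot = t % spd
    annual = cfg.annual_amplitude * np.sin(2 * np.pi * day / 365.25)
    diurnal = cfg.diurnal_amplitude * np.sin(2 * np.pi * (slot - cfg.diurnal_phase) / spd)

    dev = np.empty(L)
    if cfg.ar1_sd > 0:
        stat_sd = cfg.ar1_sd / np.sqrt(1.0 - cfg.ar1_phi ** 2)
        dev[0] = rng.normal(0.0, stat_sd)
        shocks = rng.normal(0.0, cfg.ar1_sd, size=L - 1)
        for i in range(1, L):
            dev[i] = cfg.ar1_phi * dev[i - 1] + shocks[i - 1]
    else:
        dev[:] = 0.0

    truth_vals = cfg.mean_temp + annual + diurnal + dev
    noise = rng.normal(0.0, cfg.obs_noise_sd, size=L) if cfg.obs_noise_sd > 0 else 0.0
    machine_vals = truth_vals + noise
    truth = RegularSeries(start_time=start_time, values=truth_vals)
    machine = RegularSeries(start_time=start_time, values=machine_vals)
    return truth, machine


def derive_manual_obs(truth: RegularSeries, anchor_slots=DEFAULT_ANCHOR_SLOTS,
                      bias: float = 0.0, noise_sd: float = 0.0,
                      seed: int = 0) -> pd.Series:
    """Manual readings: truth + bias + iid noise at each anchor slot daily.

    Returns a sparse timestamp-indexed series (one entry per day per anchor).
    """
    rng = np.random.default_rng(seed)
    spd = truth.slots_per_day
    n_days = len(truth) // spd
    anchors = sorted(anchor_slots)
    pos = (np.arange(n_days)[:, None] * spd + np.array(anchors)[None, :]).ravel()
    pos = pos[pos < len(truth)]
    vals = truth.values[pos] + bias
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    ts = truth.timestamps()[pos]
    return pd.Series(vals, index=ts, name="manual")


def inject_gap(machine: RegularSeries, gap: GapSpec) -> RegularSeries:
    """Remove all ``48·m`` machine values of the gap days (set to missing)."""
    spd = machine.slots_per_day
    n_days = len(machine) // spd
    if gap.gap_start_day < 0 or gap.gap_end_day > n_days:
        raise ValueError(f"gap days [{gap.gap_start_day}, {gap.gap_end_day}) "
                         f"outside series of {n_days} days")
    if gap.gap_start_day < gap.s or gap.gap_end_day + gap.s > n_days:
        raise ValueError(f"gap needs s={gap.s} fully observed context days on each side")
    out = machine.copy()
    out.values[gap.gap_start_day * spd:gap.gap_end_day * spd] = np.nan
    return out
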