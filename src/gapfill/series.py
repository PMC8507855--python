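"""Core domain types for regularly sampled temperature series.

A :class:`RegularSeries` is a half-hourly (by default) univariate series with
explicit missingness: internally ``NaN`` is the missing sentinel, and a
:class:`MaskSeries` carries the corresponding 0/1 observation mask (1 =
observed). Series are segmented into day-long blocks of ``slots_per_day``
slots (48 for half-hourly data), from which masked rolling-window training
samples are cut.

The gap regime this package targets: a contiguous run of ``m`` whole days of
missing machine observations, inside which only a few fixed "anchor" slots
per day carry values — low-frequency manual readings taken in the morning,
at midday and in the evening (default slots {16, 27, 39}, i.e. 08:00, 13:30
and 19:30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DEFAULT_ANCHOR_SLOTS = frozenset({16, 27, 39})


@dataclass
class RegularSeries:
    """Regularly sampled univariate series; NaN marks a missing value."""

    start_time: pd.Timestamp
    values: np.ndarray
    step: pd.Timedelta = pd.Timedelta(minutes=30)

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.step = pd.Timedelta(self.step)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        day = pd.Timedelta(days=1)
        if day % self.step != pd.Timedelta(0):
            raise ValueError(f"step {self.step} does not divide one day evenly")

    def __len__(self) -> int:
        return self.values.size

    @property
    def slots_per_day(self) -> int:
        return int(pd.Timedelta(days=1) // self.step)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq=self.step)

    def is_day_aligned(self) -> bool:
        return (self.start_time - self.start_time.normalize()) % self.step == pd.Timedelta(0) \
            and self.start_time == self.start_time.normalize()

    def copy(self) -> "RegularSeries":
        return replace(self, values=self.values.copy())


@dataclass
class MaskSeries:
    """Binary observation mask aligned with a RegularSeries (1 = observed)."""

    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")

    def __len__(self) -> int:
        return self.bits.size


@dataclass
class DaySegment:
    """One day of a segmented series: slots_per_day values + mask bits."""

    values: np.ndarray
    mask: np.ndarray
    day_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.values.shape != self.mask.shape:
            raise ValueError("segment values and mask must have equal length")

    @property
    def is_full(self) -> bool:
        return bool(self.mask.all())


@dataclass
class SegmentedSeries:
    segments: list[DaySegment]
    slots_per_day: int = 48

    @property
    def n_days(self) -> int:
        return len(self.segments)

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """Reassemble (values, mask) arrays; exact inverse of segment_days."""
        values = np.concatenate([s.values for s in self.segments])
        mask = np.concatenate([s.mask for s in self.segments])
        return values, mask


@dataclass(frozen=True)
class GapSpec:
    """A long gap of ``m`` whole days with ``s`` context days on each side."""

    gap_start_day: int
    m: int
    s: int = 14
    anchor_slots: frozenset = DEFAULT_ANCHOR_SLOTS

    def __post_init__(self):
        object.__setattr__(self, "anchor_slots", frozenset(self.anchor_slots))
        if self.m < 1 or self.s < 1:
            raise ValueError("gap length m and context s must each be >= 1")
        if any((a < 0 or a > 47) for a in self.anchor_slots):
            raise ValueError("anchor slots must lie in [0, 47]")

    @property
    def w(self) -> int:
        """Rolling-window length in days: m + 2s."""
        return self.m + 2 * self.s

    @property
    def gap_end_day(self) -> int:
        return self.gap_start_day + self.m


@dataclass
class WindowSample:
    """One rolling-window sample: s full days, m anchor-masked days, s full days.

    ``loss_mask`` marks the artificially hidden positions where training error
    is scored; by construction ``loss_mask & input_mask == 0``.
    """

    input_values: np.ndarray   # (w, slots) with NaN at masked positions
    input_mask: np.ndarray     # (w, slots) uint8
    target_values: np.ndarray  # (w, slots) full truth
    loss_mask: np.ndarray      # (w, slots) uint8
    start_day: int = 0


@dataclass
class CalibrationModel:
    """Affine manual -> machine map fitted by ordinary least squares."""

    slope: float
    intercept: float
    n_pairs: int
    residual_sd: float

    def apply(self, manual_values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(manual_values, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_mask(series: RegularSeries) -> MaskSeries:
    """Observation mask: bit i is 0 exactly where value i is missing."""
    return MaskSeries(bits=(~np.isnan(series.values)).astype(np.uint8))


def segment_days(series: RegularSeries, mask: MaskSeries | None = None) -> SegmentedSeries:
    """Split a day-aligned series into consecutive day segments."""
    spd = series.slots_per_day
    n = len(series)
    if n % spd != 0:
        raise ValueError(
            f"series length {n} is not divisible by {spd} slots/day "
            f"(remainder {n % spd})")
    if not series.is_day_aligned():
        raise ValueError(f"series must start at slot 0 of a day, got {series.start_time}")
    if mask is None:
        mask = build_mask(series)
    if len(mask) != n:
        raise ValueError("mask length does not match series length")
    vals = series.values.reshape(-1, spd)
    bits = mask.bits.reshape(-1, spd)
    segments = [DaySegment(values=vals[j].copy(), mask=bits[j].copy(), day_index=j)
                for j in range(n // spd)]
    return SegmentedSeries(segments=segments, slots_per_day=spd)


def apply_anchor_pattern(seg: DaySegment, anchor_slots) -> DaySegment:
    """Hide a full day down to its anchor slots (training-sample masking)."""
    if not seg.is_full:
        raise ValueError("anchor pattern applies to fully observed day segments only")
    anchors = sorted(anchor_slots)
    values = np.full_like(seg.values, np.nan)
    mask = np.zeros_like(seg.mask)
    if anchors:
        values[anchors] = seg.values[anchors]
        mask[anchors] = 1
    return DaySegment(values=values, mask=mask, day_index=seg.day_index)


def make_windows(seg_series: SegmentedSeries, gap: GapSpec, stride: int = 1) -> list[WindowSample]:
    """Cut masked rolling-window samples from a gap-free stretch of days.

    Each sample spans ``w = m + 2s`` days: the first and last ``s`` days are
    left fully observed, the middle ``m`` days are reduced to the anchor
    pattern, and the loss mask marks exactly the hidden middle positions.
    """
    w = gap.w
    n_days = seg_series.n_days
    if n_days < w:
        raise ValueError(f"need at least w={w} days, got {n_days}")
    if not all(s.is_full for s in seg_series.segments):
        raise ValueError("training windows require fully observed days")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    spd = seg_series.slots_per_day
    full = np.stack([s.values for s in seg_series.segments])  # (n_days, spd)
    anchors = sorted(gap.anchor_slots)
    anchor_bits = np.zeros(spd, dtype=np.uint8)
    anchor_bits[anchors] = 1

    samples = []
    for start in range(0, n_days - w + 1, stride):
        target = full[start:start + w].copy()
        input_mask = np.ones((w, spd), dtype=np.uint8)
        input_mask[gap.s:gap.s + gap.m] = anchor_bits
        input_values = np.where(input_mask == 1, target, np.nan)
        loss_mask = np.zeros((w, spd), dtype=np.uint8)
        loss_mask[gap.s:gap.s + gap.m] = 1 - anchor_bits
        samples.append(WindowSample(input_values=input_values, input_mask=input_mask,
                                    target_values=target, loss_mask=loss_mask,
                                    start_day=start))
    return samples


def fit_manual_calibration(manual: np.ndarray, machine: np.ndarray) -> CalibrationModel:
    """OLS affine fit machine ≈ slope * manual + intercept on matched pairs."""
    manual = np.asarray(manual, dtype=float)
    machine = np.asarray(machine, dtype=float)
    ok = ~(np.isnan(manual) | np.isnan(machine))
    manual, machine = manual[ok], machine[ok]
    n = manual.size
    if n < 2:
        raise ValueError(f"need >= 2 matched pairs, got {n}")
    if np.ptp(manual) == 0:
        raise ValueError("manual observations have zero variance; slope unidentifiable")
    X = np.column_stack([manual, np.ones(n)])
    coef, *_ = np.linalg.lstsq(X, machine, rcond=None)
    resid = machine - X @ coef
    ddof = 2 if n > 2 else 1
    residual_sd = float(np.sqrt((resid ** 2).sum() / (n - ddof))) if n > ddof else 0.0
    return CalibrationModel(slope=float(coef[0]), intercept=float(coef[1]),
                            n_pairs=n, residual_sd=residual_sd)


def insert_anchors(series_with_gap: RegularSeries, manual: pd.Series,
                   cal: CalibrationModel | None, gap: GapSpec
                   ) -> tuple[RegularSeries, MaskSeries]:
    """Place calibrated manual readings at the anchor slots of the gap days.

    ``manual`` is a sparse timestamp-indexed series. A missing manual reading
    leaves its slot missing and emits a warning. Values outside the gap are
    never touched.
    """
    out = series_with_gap.copy()
    spd = out.slots_per_day
    if cal is None:
        cal = CalibrationModel(slope=1.0, intercept=0.0, n_pairs=0, residual_sd=0.0)
    manual = manual.dropna()
    for day in range(gap.gap_start_day, gap.gap_end_day):
        for slot in sorted(gap.anchor_slots):
            pos = day * spd + slot
            if pos >= len(out):
                raise ValueError("gap extends past end of series")
            ts = out.start_time + pos * out.step
            if ts in manual.index:
                out.values[pos] = cal.apply(manual.loc[ts])
            else:
                warnings.warn(f"no manual observation at {ts}; anchor slot stays missing")
    return out, build_mask(out)


def prefill_short_gaps(series: RegularSeries, max_gap: int = 48,
                       ssm_spec=None) -> RegularSeries:
    """Fill short missing runs (<= max_gap slots) by Kalman smoothing.

    Long gaps are left untouched for the sequence models; observed values are
    never altered. ``ssm_spec`` is a state-space family spec understood by
    :func:`gapfill.kalman.impute_kalman` (default: an ARIMA(2,1,1) family,
    refitted to the observed part of the series).
    """
    from .kalman import ArimaSpec, impute_kalman

    missing = np.isnan(series.values)
    if not missing.any():
        return series.copy()
    # identify short runs
    runs = _missing_runs(missing)
    short = [(a, b) for a, b in runs if (b - a) <= max_gap]
    if not short:
        return series.copy()
    if ssm_spec is None:
        ssm_spec = ArimaSpec(p=2, d=1, q=1)
    result = impute_kalman(series, ssm_spec)
    out = series.copy()
    for a, b in short:
        out.values[a:b] = result.filled[a:b]
    return out


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of contiguous missing runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))
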