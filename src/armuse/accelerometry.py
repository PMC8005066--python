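"""Raw dual-wrist accelerometry -> epoch counts -> movement time metrics.

Processing chain, in order:

1. :func:`bandpass_filter` — 0.25–2.5 Hz band-pass (4th-order Butterworth,
   zero phase) removes gravity and high-frequency content.
2. :func:`epoch_counts` — rectified filtered acceleration is summed within
   2-s epochs (60 samples at 30 Hz) and converted to integer activity
   counts with an open calibration of 0.01664 g per count.  This is a
   documented surrogate for the device manufacturer's proprietary count
   conversion, anchored at the same published calibration point.
3. :func:`resultant` — per-epoch Euclidean norm of the three axis counts.
4. :func:`detect_nonwear` — a maximal run of >= 3 h in which every epoch's
   resultant count stays below the movement threshold is treated as the
   device being off-wrist.
5. :func:`classify_epochs` — with a movement threshold of 2 counts on the
   resultant, each epoch in which both devices were worn is unimanual
   right, unimanual left, bimanual, or no movement.
6. :func:`time_metrics` / :func:`daily_summary` — movement epochs are
   summed (2 s each) into TimeR / TimeL / TimeB per interval or per local
   calendar day, normalised by daily wearing time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "EPOCH_LENGTH_S",
    "STEP_G",
    "MOVEMENT_THRESHOLD",
    "NONWEAR_MIN_HOURS",
    "Category",
    "RawRecording",
    "EpochSeries",
    "WearMask",
    "TimeMetrics",
    "read_raw_csv",
    "write_raw_csv",
    "align_recordings",
    "bandpass_filter",
    "epoch_counts",
    "resultant",
    "detect_nonwear",
    "classify_epochs",
    "time_metrics",
    "daily_summary",
]

#: Epoch length in seconds.
EPOCH_LENGTH_S = 2.0
#: Count calibration: one activity count per 0.01664 g of sustained
#: rectified acceleration.
STEP_G = 0.01664
#: Movement threshold on the resultant count (inclusive, >= 2 is movement).
MOVEMENT_THRESHOLD = 2.0
#: Minimum duration of a below-threshold run to call non-wear.
NONWEAR_MIN_HOURS = 3.0
#: Default waking-day length (hours) used as the adherence denominator.
WAKING_HOURS = 17.0


class Category(IntEnum):
    """Per-epoch movement classification."""

    INVALID = -1  # at least one wrist not worn
    NO_MOVEMENT = 0
    UNI_RIGHT = 1
    UNI_LEFT = 2
    BIMANUAL = 3


@dataclass
class RawRecording:
    """One wrist's contiguous tri-axial acceleration stream.

    Parameters
    ----------
    wrist : {"right", "left"}
    start_time : pandas.Timestamp
        Timezone-aware time of the first sample.
    samples : ndarray of shape (n, 3)
        Acceleration in g, axis order (x, y, z).
    sample_rate : float
        Samples per second (default 30).
    """

    wrist: str
    start_time: pd.Timestamp
    samples: np.ndarray
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.wrist not in ("right", "left"):
            raise ValueError(f"wrist must be 'right' or 'left', got {self.wrist!r}")
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            raise ValueError("start_time must be timezone-aware")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.samples.shape[0] == 0:
            raise ValueError("recording contains no samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)


@dataclass
class EpochSeries:
    """Per-epoch integer activity counts for one wrist.

    ``counts`` has shape (n_epochs, 3); ``resultant`` is the per-epoch
    Euclidean norm of the axis counts.  The epoch grid is contiguous and
    anchored at ``start_time``; epochs are half-open ``[t, t + 2 s)``.
    """

    wrist: str
    start_time: pd.Timestamp
    counts: np.ndarray
    epoch_length: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_epochs, 3)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.counts.shape[0]

    @property
    def resultant(self) -> np.ndarray:
        return resultant(self.counts[:, 0], self.counts[:, 1], self.counts[:, 2])

    @property
    def epoch_times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_length, unit="s"
        )


@dataclass
class WearMask:
    """Per-epoch wear flags for both wrists on a shared grid."""

    wear_right: np.ndarray
    wear_left: np.ndarray

    def __post_init__(self) -> None:
        self.wear_right = np.asarray(self.wear_right, dtype=bool)
        self.wear_left = np.asarray(self.wear_left, dtype=bool)
        if self.wear_right.shape != self.wear_left.shape:
            raise ValueError("wear masks must share the epoch grid")

    @property
    def combined(self) -> np.ndarray:
        """Epochs usable for analysis: both devices worn."""
        return self.wear_right & self.wear_left


@dataclass
class TimeMetrics:
    """Summed movement time (seconds) over an interval.

    ``time_r + time_l + time_b + no_movement_s == wearing_time_s`` always
    holds; every field is a multiple of the epoch length.
    """

    time_r: float
    time_l: float
    time_b: float
    wearing_time_s: float
    interval: tuple | None = None

    @property
    def no_movement_s(self) -> float:
        return self.wearing_time_s - self.time_r - self.time_l - self.time_b


# ---------------------------------------------------------------------------
# raw CSV dialect


def write_raw_csv(recording: RawRecording, path: str | Path) -> None:
    """Write one wrist's raw stream in the header-comment CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# wrist: {recording.wrist}\n")
        fh.write(f"# start_time: {recording.start_time.isoformat()}\n")
        fh.write(f"# sample_rate_hz: {recording.sample_rate:g}\n")
        pd.DataFrame(recording.samples, columns=["x", "y", "z"]).to_csv(
            fh, index=False, float_format="%.5f"
        )


def read_raw_csv(path: str | Path) -> RawRecording:
    """Parse a raw accelerometry CSV written by :func:`write_raw_csv`.

    The dialect mirrors a raw ActiGraph-style export: a small comment
    header carrying wrist label, ISO 8601 start time and sample rate,
    then one x,y,z row per sample in g.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            n_header += 1
    for key in ("wrist", "start_time", "sample_rate_hz"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field '{key}'")
    data = pd.read_csv(path, skiprows=n_header)
    missing = {"x", "y", "z"} - set(data.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if data[["x", "y", "z"]].isna().any().any():
        raise ValueError(f"{path}: stream contains missing samples")
    return RawRecording(
        wrist=meta["wrist"],
        start_time=pd.Timestamp(meta["start_time"]),
        samples=data[["x", "y", "z"]].to_numpy(float),
        sample_rate=float(meta["sample_rate_hz"]),
    )


def align_recordings(
    right: RawRecording, left: RawRecording
) -> tuple[RawRecording, RawRecording]:
    """Trim two wrist streams onto a shared whole-second epoch anchor.

    Both streams are cut to start at the later of the two start times,
    rounded up to a whole second, and to the same number of samples.  A
    residual offset below half a sample period is absorbed silently; the
    devices are assumed clock-synchronized beyond that.
    """
    if right.sample_rate != left.sample_rate:
        raise ValueError("sample rates differ between wrists")
    anchor = max(right.start_time, left.start_time).ceil("s")

    def _trim(rec: RawRecording) -> np.ndarray:
        offset_s = (anchor - rec.start_time).total_seconds()
        n_skip = int(round(offset_s * rec.sample_rate))
        if abs(n_skip - offset_s * rec.sample_rate) > 0.5:
            raise ValueError("start-time offset is not on the sample grid")
        return rec.samples[n_skip:]

    r_samples, l_samples = _trim(right), _trim(left)
    n = min(len(r_samples), len(l_samples))
    if n == 0:
        raise ValueError("streams do not overlap in time")
    mk = lambda rec, s: RawRecording(rec.wrist, anchor, s[:n], rec.sample_rate)
    return mk(right, r_samples), mk(left, l_samples)


# ---------------------------------------------------------------------------
# signal processing


def bandpass_filter(
    recording: RawRecording | np.ndarray,
    sample_rate: float | None = None,
    low: float = 0.25,
    high: float = 2.5,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass over each axis.

    ``order`` is the overall filter order (4 = the band-pass built from a
    2nd-order low/high prototype); the filter is applied forward-backward
    so the passband gain is the squared single-pass magnitude and phase is
    zero.  A constant (gravity) input maps to numerically zero.
    """
    if isinstance(recording, RawRecording):
        signal, fs = recording.samples, recording.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate is required for array input")
        signal, fs = np.asarray(recording, float), float(sample_rate)
    if fs <= 2.0 * high:
        raise ValueError(
            f"sample rate {fs} Hz must exceed twice the upper corner {high} Hz"
        )
    if order % 2 != 0:
        raise ValueError("order must be even for a band-pass realisation")
    b, a = butter(order // 2, [low, high], btype="bandpass", fs=fs)
    # filtfilt's default edge padding needs a minimum signal length
    padlen = 3 * (max(len(a), len(b)) - 1)
    if signal.shape[0] <= padlen:
        raise ValueError(f"signal too short to filter (need > {padlen} samples)")
    return filtfilt(b, a, signal, axis=0)


def epoch_counts(
    filtered: np.ndarray,
    start_time: pd.Timestamp,
    wrist: str,
    sample_rate: float = 30.0,
    epoch_length: float = EPOCH_LENGTH_S,
    step_g: float = STEP_G,
) -> EpochSeries:
    """Convert band-passed acceleration to integer per-epoch activity counts.

    Per axis and per epoch of ``n = sample_rate * epoch_length`` samples::

        count = floor( sum_i |a_i| / (n * step_g) )

    i.e. the rectified mean acceleration in units of ``step_g``, floored to
    an integer.  A sustained rectified mean of exactly one ``step_g``
    yields one count, anchoring the open conversion to the published
    0.01664 g-per-count calibration.  The trailing partial epoch, if any,
    is dropped.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2 or filtered.shape[1] != 3:
        raise ValueError("filtered signal must have shape (n, 3)")
    n_per = int(round(sample_rate * epoch_length))
    n_epochs = filtered.shape[0] // n_per
    if n_epochs == 0:
        raise ValueError("signal shorter than one epoch")
    clipped = filtered[: n_epochs * n_per]
    if not np.all(np.isfinite(clipped)):
        bad = np.unique(np.nonzero(~np.isfinite(clipped))[0] // n_per)
        raise ValueError(f"non-finite samples in epoch(s) {bad.tolist()}")
    sums = np.abs(clipped).reshape(n_epochs, n_per, 3).sum(axis=1)
    # tiny guard so a rectified mean of exactly k*step_g floors to k despite
    # floating-point summation error
    counts = np.floor(sums / (n_per * step_g) + 1e-9).astype(np.int64)
    return EpochSeries(
        wrist=wrist, start_time=pd.Timestamp(start_time), counts=counts,
        epoch_length=epoch_length,
    )


def resultant(
    counts_x: np.ndarray, counts_y: np.ndarray, counts_z: np.ndarray
) -> np.ndarray:
    """Element-wise Euclidean norm of the three axis counts."""
    x, y, z = (np.asarray(v, dtype=float) for v in (counts_x, counts_y, counts_z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series lengths differ")
    return np.sqrt(x**2 + y**2 + z**2)


def detect_nonwear(
    series: EpochSeries | np.ndarray,
    threshold: float = MOVEMENT_THRESHOLD,
    min_duration_hours: float = NONWEAR_MIN_HOURS,
    epoch_length: float = EPOCH_LENGTH_S,
) -> np.ndarray:
    """Per-epoch wear flags for one wrist (True = worn).

    An epoch is non-wear iff it lies inside a maximal run of consecutive
    epochs whose resultant count is below ``threshold`` and whose total
    duration is at least ``min_duration_hours``.  Runs shorter than the
    minimum are indistinguishable from genuine stillness and stay "worn".
    """
    if isinstance(series, EpochSeries):
        values = series.resultant
        epoch_length = series.epoch_length
    else:
        values = np.asarray(series, dtype=float)
    still = values < threshold
    wear = np.ones(len(values), dtype=bool)
    min_epochs = int(np.ceil(min_duration_hours * 3600.0 / epoch_length))
    if len(values) == 0:
        return wear
    # maximal runs of consecutive still epochs
    edges = np.flatnonzero(np.diff(still.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [len(still)]))
    for s, e in zip(starts, ends):
        if still[s] and (e - s) >= min_epochs:
            wear[s:e] = False
    return wear


def classify_epochs(
    right: EpochSeries,
    left: EpochSeries,
    mask: WearMask | None = None,
    threshold: float = MOVEMENT_THRESHOLD,
) -> np.ndarray:
    """Classify each epoch by which wrists moved.

    Movement on a wrist means resultant count >= ``threshold`` (inclusive).
    Exactly one moving wrist gives a unimanual epoch, both give bimanual,
    neither gives no-movement.  Epochs where either device was off-wrist
    are ``Category.INVALID`` and excluded from all time metrics.

    Returns an int8 array of :class:`Category` codes.
    """
    if right.n_epochs != left.n_epochs:
        raise ValueError(
            f"epoch grids differ: right {right.n_epochs}, left {left.n_epochs}"
        )
    if abs((right.start_time - left.start_time).total_seconds()) > right.epoch_length / 2:
        raise ValueError("epoch grids are not aligned; align recordings first")
    r_move = right.resultant >= threshold
    l_move = left.resultant >= threshold
    codes = np.full(right.n_epochs, Category.NO_MOVEMENT, dtype=np.int8)
    codes[r_move & ~l_move] = Category.UNI_RIGHT
    codes[~r_move & l_move] = Category.UNI_LEFT
    codes[r_move & l_move] = Category.BIMANUAL
    if mask is not None:
        combined = mask.combined
        if len(combined) != len(codes):
            raise ValueError("wear mask length does not match the epoch grid")
        codes[~combined] = Category.INVALID
    return codes


def time_metrics(
    classification: np.ndarray,
    epoch_times: pd.DatetimeIndex | None = None,
    interval: tuple | None = None,
    epoch_length: float = EPOCH_LENGTH_S,
) -> TimeMetrics:
    """Sum classified epochs into TimeR / TimeL / TimeB seconds.

    ``interval``, if given, is a half-open ``[start, end)`` pair of
    timestamps; epochs whose start time falls inside it are summed
    (``epoch_times`` is then required).  An empty selection yields
    all-zero metrics with zero wearing time.
    """
    codes = np.asarray(classification)
    if interval is not None:
        if epoch_times is None:
            raise ValueError("epoch_times required when interval is given")
        start, end = interval
        sel = (epoch_times >= start) & (epoch_times < end)
        codes = codes[np.asarray(sel)]
    valid = codes != Category.INVALID
    return TimeMetrics(
        time_r=float(np.sum(codes == Category.UNI_RIGHT)) * epoch_length,
        time_l=float(np.sum(codes == Category.UNI_LEFT)) * epoch_length,
        time_b=float(np.sum(codes == Category.BIMANUAL)) * epoch_length,
        wearing_time_s=float(np.sum(valid)) * epoch_length,
        interval=interval,
    )


def daily_summary(
    classification: np.ndarray,
    epoch_times: pd.DatetimeIndex,
    waking_hours: float = WAKING_HOURS,
    participant_id: str | None = None,
    epoch_length: float = EPOCH_LENGTH_S,
) -> pd.DataFrame:
    """Per local-calendar-day wearing time, TimeR/L/B and adherence.

    Days run midnight to midnight in the recording's local time zone; day
    1 is the calendar day of the first valid (both-worn) epoch.  Percent
    columns normalise each metric by that day's wearing time and are
    missing (NaN) on days with zero wear.  ``adherence_pct`` is wearing
    time as a percentage of the configurable waking-hours denominator.
    """
    codes = np.asarray(classification)
    if len(codes) != len(epoch_times):
        raise ValueError("classification and epoch_times lengths differ")
    dates = pd.Series(epoch_times.date)
    valid_dates = dates[codes != Category.INVALID]
    first_day = valid_dates.min() if not valid_dates.empty else dates.min()
    rows = []
    for date, idx in dates.groupby(dates).groups.items():
        m = time_metrics(codes[np.asarray(idx)], epoch_length=epoch_length)
        wearing_h = m.wearing_time_s / 3600.0
        if m.wearing_time_s > 0:
            pct = {
                "time_r_pct": 100.0 * m.time_r / m.wearing_time_s,
                "time_l_pct": 100.0 * m.time_l / m.wearing_time_s,
                "time_b_pct": 100.0 * m.time_b / m.wearing_time_s,
            }
        else:
            pct = {"time_r_pct": np.nan, "time_l_pct": np.nan, "time_b_pct": np.nan}
        rows.append(
            {
                "participant_id": participant_id,
                "date": date,
                "day": (date - first_day).days + 1,
                "wearing_hours": wearing_h,
                "time_r_s": m.time_r,
                "time_l_s": m.time_l,
                "time_b_s": m.time_b,
                **pct,
                "adherence_pct": 100.0 * wearing_h / waking_hours,
            }
        )
    out = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    return out
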