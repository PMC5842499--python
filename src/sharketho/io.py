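"""Reading, writing and epoch-aligning tag time series and behaviour labels.

Acceleration is recorded on three orthogonal body axes — surge (x,
anterior–posterior), heave (y, dorsal–ventral) and sway (z, lateral) — in
units of g at a fast rate (typically 30 Hz), with optional depth (m) and
temperature (°C) channels at a slow rate (typically 1 Hz).  Behaviour labels
live on non-overlapping 1-s epochs aligned to the series start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical behaviour vocabulary, in canonical order.  ``swim`` is the
#: background state; ties in classifier probabilities break to the earlier
#: class in this list.
CLASSES: tuple[str, ...] = ("swim", "headshake", "rest", "chafe", "burst")


class SeriesFormatError(ValueError):
    """Raised when a tag file violates the expected layout or timing."""


@dataclass
class TriaxialSeries:
    """A gap-free tri-axial acceleration record with optional slow channels.

    Parameters
    ----------
    start_time : pandas.Timestamp
        Time of the first fast sample.
    rate_hz : float
        Fast sampling rate (samples per second), default 30.
    x, y, z : ndarray
        Surge, heave and sway acceleration in g.  Equal length, at least
        one second of data.
    depth, temp : ndarray, optional
        Depth (m) and temperature (°C) at ``slow_rate_hz``.
    """

    start_time: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float = 30.0
    depth: np.ndarray | None = None
    temp: np.ndarray | None = None
    slow_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        for name in ("x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.rate_hz <= 0:
            raise SeriesFormatError(f"rate_hz must be positive, got {self.rate_hz}")
        n = len(self.x)
        for name in ("y", "z"):
            m = len(getattr(self, name))
            if m != n:
                raise SeriesFormatError(
                    f"channel {name} has length {m}, expected {n} (same as x)"
                )
        if n < self.rate_hz:
            raise SeriesFormatError(
                f"series holds {n} samples, less than one second at {self.rate_hz} Hz"
            )
        for name in ("x", "y", "z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise SeriesFormatError(f"channel {name} contains missing samples")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def n_epochs(self) -> int:
        """Number of whole 1-s epochs; trailing partial seconds are dropped."""
        return int(self.n_samples // round(self.rate_hz))

    def times(self) -> pd.DatetimeIndex:
        offsets_ns = np.round(np.arange(self.n_samples) * 1e9 / self.rate_hz).astype("int64")
        return self.start_time + pd.to_timedelta(offsets_ns, unit="ns")


@dataclass
class LabelTrack:
    """One behaviour code per 1-s epoch."""

    labels: np.ndarray
    epoch_start: pd.Timestamp

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.epoch_start = pd.Timestamp(self.epoch_start)
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"labels outside the behaviour vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def epoch_times(self) -> pd.DatetimeIndex:
        return self.epoch_start + pd.to_timedelta(np.arange(len(self)), unit="s")


DEFAULT_SCHEMA = {
    "time": "time",
    "x": "x",
    "y": "y",
    "z": "z",
    "depth": "depth",
    "temp": "temp",
}


def read_series(
    path,
    schema: dict[str, str] | None = None,
    rate_hz: float | None = None,
    slow_rate_hz: float = 1.0,
) -> TriaxialSeries:
    """Read a CSV tag export into a validated :class:`TriaxialSeries`.

    The file must carry an ISO-8601 timestamp column and x/y/z acceleration
    columns in g; optional depth/temp columns are sampled at the slow rate
    (missing entries between slow samples are allowed).  The sampling
    interval is inferred from the first two timestamps unless ``rate_hz``
    is given, and every gap is checked: a jump of more than one sample
    period is a load error naming the first offending row.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("time", "x", "y", "z"):
        if colmap[key] not in df.columns:
            raise SeriesFormatError(f"missing required column {colmap[key]!r} in {path}")
    times = pd.to_datetime(df[colmap["time"]], format="ISO8601")
    dt = times.diff().dt.total_seconds().to_numpy()[1:]
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0)) + 1
        raise SeriesFormatError(f"non-monotone timestamps at row {i} in {path}")
    if rate_hz is None:
        # infer from the full span so per-sample nanosecond rounding cancels
        span = (times.iloc[-1] - times.iloc[0]).total_seconds()
        rate_hz = round((len(times) - 1) / span, 6)
    period = 1.0 / rate_hz
    gaps = np.nonzero(dt > 1.5 * period)[0]
    if gaps.size:
        i = int(gaps[0]) + 1
        raise SeriesFormatError(
            f"gap of {dt[gaps[0]]:.4f} s (> one {period:.4f} s sample period) "
            f"before row {i} in {path}"
        )

    def _nan_guard(arr, name):
        if np.any(~np.isfinite(arr)):
            raise SeriesFormatError(f"missing samples in channel {name} of {path}")
        return arr

    kwargs = {}
    for ch in ("depth", "temp"):
        col = colmap[ch]
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            slow = vals[~np.isnan(vals)]
            if slow.size:
                kwargs[ch] = slow
    return TriaxialSeries(
        start_time=times.iloc[0],
        x=_nan_guard(df[colmap["x"]].to_numpy(dtype=float), "x"),
        y=_nan_guard(df[colmap["y"]].to_numpy(dtype=float), "y"),
        z=_nan_guard(df[colmap["z"]].to_numpy(dtype=float), "z"),
        rate_hz=rate_hz,
        slow_rate_hz=slow_rate_hz,
        **kwargs,
    )


def write_series(series: TriaxialSeries, path) -> None:
    """Write a series to the CSV layout understood by :func:`read_series`.

    Fast channels are written densely; slow channels are placed on the first
    fast row of each slow interval and left blank elsewhere, preserving the
    native 1 Hz storage.  The round trip is value-exact for the
    acceleration channels.
    """
    times = series.times()
    df = pd.DataFrame(
        {
            # nanosecond ISO stamps: exact for rates that do not divide 1 us
            "time": [t.isoformat() for t in times],
            "x": series.x,
            "y": series.y,
            "z": series.z,
        }
    )
    stride = int(round(series.rate_hz / series.slow_rate_hz))
    for ch in ("depth", "temp"):
        vals = getattr(series, ch)
        if vals is not None:
            col = np.full(series.n_samples, np.nan)
            idx = np.arange(len(vals)) * stride
            idx = idx[idx < series.n_samples]
            col[idx] = np.asarray(vals)[: len(idx)]
            df[ch] = col
    df.to_csv(path, index=False, float_format="%.17g")


def align_labels(
    series: TriaxialSeries,
    annotations: list[tuple] | None = None,
    background: str = "swim",
) -> LabelTrack:
    """Rasterise timed behaviour annotations onto the series' 1-s epochs.

    ``annotations`` is a list of ``(start, end, behaviour)`` with timestamps
    (or second offsets from the series start).  Seconds not covered by any
    annotation take the background state (``swim``).  Where an annotation
    covers an epoch only partially, the epoch takes the behaviour covering
    at least half of it, later-starting annotations painting over earlier
    ones; coverage ties break to the earlier annotation.
    """
    n = series.n_epochs
    labels = np.array([background] * n, dtype=object)
    if not annotations:
        return LabelTrack(labels=labels, epoch_start=series.start_time)
    # coverage[i]: fraction of epoch i covered by the currently winning annotation
    coverage = np.zeros(n)
    end_limit = series.start_time + pd.Timedelta(seconds=series.duration_s)
    for start, end, behav in annotations:
        if behav not in CLASSES:
            raise ValueError(f"behaviour {behav!r} outside the vocabulary")
        if not isinstance(start, pd.Timestamp):
            try:
                start = series.start_time + pd.Timedelta(seconds=float(start))
                end = series.start_time + pd.Timedelta(seconds=float(end))
            except (TypeError, ValueError):
                start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start < series.start_time or end > end_limit or end < start:
            raise ValueError(
                f"annotation ({start}, {end}, {behav}) outside series extent "
                f"[{series.start_time}, {end_limit}]"
            )
        t0 = (start - series.start_time).total_seconds()
        t1 = (end - series.start_time).total_seconds()
        for epoch in range(int(np.floor(t0)), min(n, int(np.ceil(t1)))):
            frac = min(t1, epoch + 1) - max(t0, epoch)
            # later-starting annotations paint over earlier ones when both
            # fully cover the epoch; partial-coverage ties keep the earlier
            if frac >= 0.5 and (frac > coverage[epoch] or frac == 1.0):
                coverage[epoch] = frac
                labels[epoch] = behav
    return LabelTrack(labels=labels, epoch_start=series.start_time)


def write_labels(track: LabelTrack, path) -> None:
    pd.DataFrame(
        {"time": track.epoch_times().strftime("%Y-%m-%dT%H:%M:%S"), "label": track.labels}
    ).to_csv(path, index=False)


def read_labels(path) -> LabelTrack:
    df = pd.read_csv(path)
    return LabelTrack(
        labels=df["label"].to_numpy(dtype=object),
        epoch_start=pd.Timestamp(df["time"].iloc[0]),
    )
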