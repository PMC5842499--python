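"""From classified seconds to hourly foraging records with tide and season.

Headshaking is used as a proxy for successful prey capture, so classifier
output is post-processed before any ecological modelling:

* predicted headshake runs shorter than 2 s are relabelled to the swim
  background (observed headshakes always lasted at least 2 s, so shorter
  runs are false positives);
* because a single prey-manipulation event varies greatly in duration and
  may contain several headshake runs, behaviour is reduced to
  presence/absence per clock hour of deployment;
* each hour receives a tidal phase (Ebb / Low / Flood / High, High and Low
  being 1 h either side of the — locally lagged — peak), a season
  (wet: April–September, dry: October–March) and the individual's ID;
* covariate collinearity is screened with generalized variance-inflation
  factors (GVIF) before model fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from sharketho.io import LabelTrack


def behaviour_runs(labels: np.ndarray, behaviour: str) -> list[tuple[int, int]]:
    """Maximal runs of ``behaviour`` as (start, length) pairs in seconds."""
    mask = np.asarray(labels, dtype=object) == behaviour
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def filter_short_headshakes(
    labels: LabelTrack, min_run_s: int = 2, behaviour: str = "headshake",
    background: str = "swim",
) -> LabelTrack:
    """Relabel sub-``min_run_s`` headshake runs to the swim background.

    Runs of at least ``min_run_s`` consecutive seconds are untouched; the
    filter never creates new headshake seconds and is idempotent.
    """
    out = labels.labels.copy()
    for start, length in behaviour_runs(out, behaviour):
        if length < min_run_s:
            out[start : start + length] = background
    return LabelTrack(labels=out, epoch_start=labels.epoch_start)


def hourly_presence(
    labels: LabelTrack,
    behaviour: str = "headshake",
    shark_id: str = "unknown",
    min_coverage_s: int = 1800,
) -> pd.DataFrame:
    """Presence/absence of a behaviour per clock hour of the track.

    Returns one row per clock hour overlapped by the track with columns
    ``shark_id, date, hour_of_day, present, n_seconds, coverage_s``.  An
    hour is *present* if it contains at least one behaviour-second —
    multiple events in an hour count the same as one.  Hours only partially
    covered at the deployment edges are kept if at least
    ``min_coverage_s`` (default 30 min) of them is recorded.
    """
    times = labels.epoch_times()
    hours = times.floor("h")
    df = pd.DataFrame({"hour_start": hours, "is_behaviour": labels.labels == behaviour})
    grouped = df.groupby("hour_start", sort=True).agg(
        n_seconds=("is_behaviour", "sum"), coverage_s=("is_behaviour", "size")
    )
    full = grouped["coverage_s"] >= 3600
    keep = full | (grouped["coverage_s"] >= min_coverage_s)
    grouped = grouped[keep]
    out = pd.DataFrame(
        {
            "shark_id": shark_id,
            "date": grouped.index.date,
            "hour_of_day": grouped.index.hour,
            "present": grouped["n_seconds"] > 0,
            "n_seconds": grouped["n_seconds"].astype(int),
            "coverage_s": grouped["coverage_s"].astype(int),
        }
    ).reset_index(names="hour_start")
    return out


def assign_tide_phase(
    times,
    peak_table: list[tuple],
    lag_h: float = 1.0,
    window_h: float = 1.0,
) -> np.ndarray:
    """Tidal phase (Ebb/Low/Flood/High) for each time, from station peaks.

    ``peak_table`` lists ``(peak_time, "high"|"low")`` tide peaks at the
    reference station, strictly alternating.  Local peaks lag the station
    by ``lag_h`` hours, so each peak is shifted by ``+lag_h`` first.  Times
    within ``window_h`` of a shifted high (low) peak are High (Low); the
    stretch from the end of a Low window to the start of the next High
    window is Flood (rising water), and High-to-Low is Ebb (falling).
    Times outside the shifted peak coverage raise an error.
    """
    peaks = sorted(
        ((pd.Timestamp(t) + pd.Timedelta(hours=lag_h), str(kind).lower())
         for t, kind in peak_table),
        key=lambda p: p[0],
    )
    if len(peaks) < 2:
        raise ValueError("peak table needs at least two alternating peaks")
    for (t0, k0), (t1, k1) in zip(peaks, peaks[1:]):
        if k0 == k1:
            raise ValueError(f"peak table does not alternate high/low at {t1}")
    times = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(times, dtype=object))))
    w = pd.Timedelta(hours=window_h)
    lo_cov = peaks[0][0] - w
    hi_cov = peaks[-1][0] + w
    out = np.empty(len(times), dtype=object)
    for i, t in enumerate(times):
        if t < lo_cov or t >= hi_cov:
            raise ValueError(
                f"time {t} outside tide-peak coverage [{lo_cov}, {hi_cov})"
            )
        phase = None
        for j, (pt, kind) in enumerate(peaks):
            if pt - w <= t < pt + w:
                phase = "High" if kind == "high" else "Low"
                break
            if t < pt - w:
                # between previous peak's window and this one
                prev_kind = peaks[j - 1][1]
                phase = "Flood" if prev_kind == "low" else "Ebb"
                break
        if phase is None:  # inside the last peak's trailing window only
            phase = "High" if peaks[-1][1] == "high" else "Low"
        out[i] = phase
    return out


def assign_season(dates) -> np.ndarray:
    """Season of each date: wet (April–September) or dry (October–March)."""
    months = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(dates, dtype=object)))).month
    return np.where((months >= 4) & (months <= 9), "wet", "dry").astype(object)


def _gvif_once(design_blocks: dict[str, np.ndarray]) -> pd.Series:
    """Fox–Monette GVIF per covariate from dummy-coded design blocks.

    For covariate *j* with correlation submatrix ``R11`` (its own columns),
    ``R22`` (all other columns) and ``R`` (all columns):
    ``GVIF_j = det(R11) det(R22) / det(R)``.
    """
    cols, owner = [], []
    for name, block in design_blocks.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] < block.shape[1]:
            block = block.T
        for k in range(block.shape[1]):
            cols.append(block[:, k])
            owner.append(name)
    X = np.column_stack(cols)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column; GVIF undefined")
    R = np.corrcoef(X, rowvar=False)
    det_r = np.linalg.det(R)
    if det_r <= 1e-12:
        raise ValueError("design is rank deficient; GVIF cannot be computed")
    owner = np.array(owner)
    out = {}
    for name in design_blocks:
        own = owner == name
        r11 = R[np.ix_(own, own)]
        r22 = R[np.ix_(~own, ~own)]
        out[name] = float(np.linalg.det(r11) * np.linalg.det(r22) / det_r)
    return pd.Series(out)


def _encode(covariates: pd.DataFrame) -> dict[str, np.ndarray]:
    blocks = {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks[name] = col.to_numpy(dtype=float)[:, None]
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            blocks[name] = dummies.to_numpy(dtype=float)
    return blocks


def gvif_screen(
    covariates: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative GVIF collinearity screen.

    Categorical covariates are dummy-coded and scored with the df-adjusted
    value ``GVIF^(1/(2 df))`` squared, which is on the same scale as an
    ordinary VIF; numeric covariates reduce to the plain VIF.  While any
    covariate scores above ``threshold``, the worst one is removed and all
    scores are recomputed.  Returns the retained covariate names and the
    score history (columns: covariate, gvif, df, adjusted_score, round,
    removed).
    """
    remaining = list(covariates.columns)
    if len(remaining) < 2:
        raise ValueError("GVIF screening needs at least two covariates")
    history = []
    round_no = 0
    while True:
        round_no += 1
        blocks = _encode(covariates[remaining])
        dfs = {k: v.shape[1] for k, v in blocks.items()}
        gvif = _gvif_once(blocks)
        adjusted = pd.Series(
            {k: gvif[k] ** (1.0 / dfs[k]) for k in gvif.index}
        )  # (GVIF^(1/(2 df)))^2, comparable to a VIF
        worst = adjusted.idxmax()
        drop = adjusted[worst] > threshold
        for k in gvif.index:
            history.append(
                {
                    "covariate": k, "gvif": gvif[k], "df": dfs[k],
                    "adjusted_score": adjusted[k], "round": round_no,
                    "removed": bool(drop and k == worst),
                }
            )
        if not drop:
            break
        warnings.warn(
            f"removing covariate {worst!r} (adjusted GVIF "
            f"{adjusted[worst]:.2f} > {threshold})",
            stacklevel=2,
        )
        remaining.remove(worst)
        if len(remaining) < 2:
            break
    return remaining, pd.DataFrame(history)


def build_hourly_records(
    presence: pd.DataFrame,
    peak_table: list[tuple],
    temps: pd.DataFrame | None = None,
    lag_h: float = 1.0,
) -> pd.DataFrame:
    """Join hourly presence with tide phase, season and optional temperature.

    ``presence`` is the output of :func:`hourly_presence` (possibly
    concatenated over individuals); tide phase is evaluated at each hour's
    midpoint.  ``temps``, if given, carries ``hour_start, mean_temp``.
    """
    rec = presence.copy()
    midpoints = pd.DatetimeIndex(rec["hour_start"]) + pd.Timedelta(minutes=30)
    rec["tide_phase"] = assign_tide_phase(midpoints, peak_table, lag_h=lag_h)
    rec["season"] = assign_season(rec["hour_start"])
    if temps is not None:
        rec = rec.merge(temps[["hour_start", "mean_temp"]], on="hour_start", how="left")
    return rec
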