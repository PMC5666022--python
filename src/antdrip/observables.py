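"""Derived quantities: interdrop intervals, increments, sizes, histograms,
and structure aspect ratios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IntervalSeries:
    """Interdrop intervals of one trial.

    ``dt[n] = t[n+1] - t[n]`` between consecutive droplets of the same
    trial; ``increments[n] = dt[n+1] - dt[n]``.  Trials with fewer than two
    events yield empty series.
    """
    dt: np.ndarray
    sizes: np.ndarray

    @property
    def increments(self) -> np.ndarray:
        if len(self.dt) < 2:
            return np.array([], dtype=int)
        return np.diff(self.dt)


def intervals_from_events(events) -> IntervalSeries:
    """Interval series of one trial's time-ordered droplet events.

    Accepts DropletEvent records or (t, size) pairs.
    """
    times, sizes = [], []
    for e in events:
        if hasattr(e, "t"):
            times.append(e.t)
            sizes.append(e.size)
        else:
            t, s = e
            times.append(t)
            sizes.append(s)
    times = np.asarray(times, dtype=int)
    if np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing in a trial")
    dt = np.diff(times) if len(times) >= 2 else np.array([], dtype=int)
    return IntervalSeries(dt=dt, sizes=np.asarray(sizes, dtype=int))


def intervals_per_trial(results) -> list[IntervalSeries]:
    """Interval series per trial (never across trial boundaries)."""
    return [intervals_from_events(r.events) for r in results]


def pooled_increment_magnitudes(series_list) -> np.ndarray:
    """Pool nonzero |increment| values across trials, for tail fitting."""
    mags = np.concatenate([np.abs(s.increments) for s in series_list]
                          or [np.array([], dtype=int)])
    return mags[mags > 0]


def pooled_sizes(series_list) -> np.ndarray:
    return np.concatenate([s.sizes for s in series_list]
                          or [np.array([], dtype=int)])


def interval_histogram(dts, bin_width: int = 1) -> pd.Series:
    """Normalised probability distribution P(DT) of pooled intervals.

    Bins are ``[k*bin_width, (k+1)*bin_width)`` indexed by their left edge;
    the returned series sums to 1 (empty for empty input).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    dts = np.asarray(dts)
    if dts.size == 0:
        return pd.Series(dtype=float)
    left = (dts // bin_width) * bin_width
    counts = pd.Series(left).value_counts().sort_index()
    return counts / counts.sum()


def aspect_ratio_track(metrics: pd.DataFrame) -> tuple[float, float]:
    """Mean maximum (width, height) of the hanging structure across trials.

    For each trial, the structure's (width, height) is sampled at the step
    where its height (depth below the rod) is largest; trials that never
    hold an inactive agent are excluded.  Returns the across-trial means.
    """
    widths, heights = [], []
    for _, df in metrics.groupby("trial"):
        df = df[df["n_inactive"] > 0]
        if df.empty:
            continue
        row = df.loc[df["height"].idxmax()]
        widths.append(row["width"])
        heights.append(row["height"])
    if not widths:
        raise ValueError("no trial contains any inactive agent")
    return float(np.mean(widths)), float(np.mean(heights))
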