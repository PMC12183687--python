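"""Cross-stream synchronization and condition-split, event-aligned averaging.

The FSCV (10 Hz frame) and electrophysiology (kHz) acquisition systems share
uniform trial-start event codes; a least-squares linear clock map between the
two timestamp streams puts both modalities on a common time base.  Trial
averages are computed per condition, pointwise over trials, with null-masked
(NaN) samples excluded from both the mean and the standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ClockMap", "TrialAverage", "sync_streams", "epoch_and_average",
           "average_trial_matrix"]


@dataclass(frozen=True)
class ClockMap:
    """Linear map t_b = slope * t_a + offset between two acquisition clocks."""

    slope: float
    offset: float
    residual_rms: float
    n_matched: int

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("clock map slope must be positive")

    def a_to_b(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.offset

    def b_to_a(self, t):
        return (np.asarray(t, dtype=float) - self.offset) / self.slope

    def inverse(self) -> "ClockMap":
        return ClockMap(slope=1.0 / self.slope, offset=-self.offset / self.slope,
                        residual_rms=self.residual_rms / self.slope,
                        n_matched=self.n_matched)


@dataclass
class TrialAverage:
    """Event-aligned per-condition mean +/- standard error over trials."""

    time: np.ndarray                       # s relative to the event
    mean: dict                             # condition -> array
    se: dict                               # condition -> array
    n: dict                                # condition -> non-null count per point
    n_trials: dict                         # condition -> included trial count
    n_dropped: int = 0                     # partial epochs discarded
    null_fraction: dict = None             # condition -> fraction of NaN points
    single_trial_conditions: tuple = ()    # SE reported as 0 for these


def sync_streams(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    code: Optional[int] = None,
    residual_tolerance_s: float = 1e-3,
) -> ClockMap:
    """Least-squares linear clock map from matched event-code pairs.

    Codes are matched by value and occurrence order (the k-th occurrence of a
    code in stream A pairs with the k-th in stream B); restrict to a single
    ``code`` (e.g., the uniform trial-start code) if given.
    """
    def _stamps(ev):
        df = ev[ev["code"] == code] if code is not None else ev
        return df.sort_values("timestamp_s").groupby("code")["timestamp_s"]

    ga, gb = _stamps(events_a), _stamps(events_b)
    ta, tb = [], []
    for c, sa in ga:
        if c not in gb.groups:
            continue
        sb = gb.get_group(c)
        m = min(len(sa), len(sb))
        ta.append(sa.to_numpy()[:m])
        tb.append(sb.to_numpy()[:m])
    if not ta:
        raise ValueError("no matching event codes between streams")
    ta = np.concatenate(ta)
    tb = np.concatenate(tb)
    if ta.size < 2:
        raise ValueError(f"need >= 2 matched codes, got {ta.size}")
    slope, offset = np.polyfit(ta, tb, 1)
    resid = tb - (slope * ta + offset)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if rms > residual_tolerance_s:
        warnings.warn(f"clock-map residual RMS {rms:.2e} s exceeds tolerance "
                      f"{residual_tolerance_s:.2e} s")
    return ClockMap(slope=float(slope), offset=float(offset),
                    residual_rms=rms, n_matched=int(ta.size))


def _mean_se(stack: np.ndarray):
    """Pointwise nan-excluding mean, SE (sd/sqrt(n), ddof=1) and counts."""
    n = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    se = np.where(n == 0, np.nan, se)
    return mean, se, n


def average_trial_matrix(
    matrix: np.ndarray,
    rel_times: np.ndarray,
    condition_labels: Optional[Sequence[str]] = None,
    n_dropped: int = 0,
    conditions: Optional[Sequence[str]] = None,
) -> TrialAverage:
    """Condition-split mean +/- SE of a prebuilt (trials x time) matrix.

    ``conditions`` fixes the reported condition set; conditions with no
    usable trials yield an all-NaN row with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = (np.asarray(condition_labels) if condition_labels is not None
              else np.array(["all"] * matrix.shape[0]))
    if conditions is None:
        conditions = pd.unique(labels)
    mean, se, counts, n_trials, nullfrac = {}, {}, {}, {}, {}
    singles = []
    for cond in conditions:
        stack = matrix[labels == cond]
        n_trials[cond] = stack.shape[0]
        if stack.shape[0] == 0:
            warnings.warn(f"no usable trials in condition {cond!r}")
            mean[cond] = np.full(rel_times.size, np.nan)
            se[cond] = np.full(rel_times.size, np.nan)
            counts[cond] = np.zeros(rel_times.size, dtype=int)
            nullfrac[cond] = np.nan
            continue
        m, s, c = _mean_se(stack)
        mean[cond], se[cond], counts[cond] = m, s, c
        nullfrac[cond] = float(np.isnan(stack).mean())
        if stack.shape[0] == 1:
            singles.append(cond)
    return TrialAverage(time=rel_times, mean=mean, se=se, n=counts,
                        n_trials=n_trials, n_dropped=n_dropped,
                        null_fraction=nullfrac,
                        single_trial_conditions=tuple(singles))


def epoch_and_average(
    times: np.ndarray,
    values: np.ndarray,
    event_times: Sequence[float],
    window: tuple = (-2.0, 6.0),
    condition_labels: Optional[Sequence[str]] = None,
) -> TrialAverage:
    """Epoch a uniformly sampled series around events and average by condition.

    The aligned grid is the series' native sampling grid; epochs extending
    past either end of the series are dropped (and counted).  NaN samples
    (nulled frames) are excluded pointwise from mean and SE; a single usable
    trial yields SE = 0 and is flagged in ``single_trial_conditions``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if window[0] >= window[1]:
        raise ValueError("window must span the event (w0 < w1)")
    dt = float(np.median(np.diff(times)))
    lo = int(round(window[0] / dt))
    hi = int(round(window[1] / dt))
    rel = np.arange(lo, hi + 1) * dt

    event_times = np.asarray(event_times, dtype=float)
    labels = (np.asarray(condition_labels) if condition_labels is not None
              else np.array(["all"] * event_times.size))
    if labels.size != event_times.size:
        raise ValueError("condition_labels must match event_times")

    rows, kept_labels, dropped = [], [], 0
    for t_ev, lab in zip(event_times, labels):
        i0 = int(round((t_ev - times[0]) / dt))
        if i0 + lo < 0 or i0 + hi >= times.size:
            dropped += 1
            continue
        rows.append(values[i0 + lo: i0 + hi + 1])
        kept_labels.append(lab)
    matrix = np.asarray(rows) if rows else np.empty((0, rel.size))
    return average_trial_matrix(matrix, rel, kept_labels or None,
                                n_dropped=dropped,
                                conditions=pd.unique(labels))
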