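"""Trace-level normalization and response summaries for plate-reader assays.

The processing order for every response is: trailing rolling-window smoothing,
division by the pre-injection baseline of the same well, division by the
matching vehicle/buffer well, then a scalar summary (peak for calcium flux,
area under/over the curve for BRET). Buffer-vs-buffer processing therefore
yields a peak of exactly 1 and areas of exactly 0, and every summary is
invariant to rescaling raw signals by any positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import KineticTrace

__all__ = [
    "ResponseValue",
    "rolling_average",
    "baseline_normalize",
    "vehicle_ratio",
    "ca_peak_response",
    "bret_ratio",
    "bret_auc_response",
    "g_dissoc_aoc",
    "antagonist_response",
]

DEFAULT_WINDOW = 10        # acquisition points (5 s at 0.5 s spacing)
DEFAULT_BASELINE_POINTS = 10
DEFAULT_HORIZON = 600.0    # seconds ("over 10 min")


@dataclass
class ResponseValue:
    well_id: str
    assay: str  # ca_peak | arr_bret_auc | g_dissoc_aoc | antagonist_peak
    value: float
    window_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"{self.well_id}: non-finite response value")


def rolling_average(trace: KineticTrace, window: int = DEFAULT_WINDOW) -> KineticTrace:
    """Trailing (causal) rolling mean over ``window`` points, per channel.

    Edge handling shrinks the window: output[i] is the mean of the points at
    indices max(0, i-window+1)..i, so the series length is preserved.
    """
    n = trace.times.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    smoothed = {
        name: pd.Series(vals).rolling(window, min_periods=1).mean().to_numpy()
        for name, vals in trace.channels.items()
    }
    return trace.replace(**smoothed)


def _baseline_slice(trace: KineticTrace, injection: float, baseline_points: int) -> slice:
    n_pre = int(np.sum(trace.times < injection))
    if n_pre < baseline_points:
        raise ValueError(
            f"{trace.well_id}: only {n_pre} samples precede injection at {injection}s "
            f"(need {baseline_points})"
        )
    return slice(n_pre - baseline_points, n_pre)


def baseline_normalize(trace: KineticTrace, injection: float | None = None,
                       baseline_points: int = DEFAULT_BASELINE_POINTS) -> KineticTrace:
    """Divide each channel by the mean of the samples just before injection."""
    if injection is None:
        injection = trace.injections[0]
    sl = _baseline_slice(trace, injection, baseline_points)
    out = {}
    for name, vals in trace.channels.items():
        base = float(np.mean(vals[sl]))
        if base <= 0:
            raise ValueError(f"{trace.well_id}: nonpositive baseline in channel {name!r}")
        out[name] = vals / base
    return trace.replace(**out)


def vehicle_ratio(norm_trace: KineticTrace, norm_buffer: KineticTrace) -> KineticTrace:
    """Pointwise ratio of a normalized trace over the matching buffer well."""
    if norm_trace.times.shape != norm_buffer.times.shape or not np.allclose(
        norm_trace.times, norm_buffer.times
    ):
        raise ValueError(
            f"time grid mismatch between {norm_trace.well_id} and {norm_buffer.well_id}"
        )
    out = {}
    for name, vals in norm_trace.channels.items():
        buf = norm_buffer.channel(name)
        if np.any(buf <= 0):
            raise ValueError(f"{norm_buffer.well_id}: nonpositive buffer values in {name!r}")
        out[name] = vals / buf
    return norm_trace.replace(**out)


def _window_params(**kwargs) -> dict:
    return dict(kwargs)


def ca_peak_response(agonist_trace: KineticTrace, buffer_trace: KineticTrace,
                     injection: float | None = None, window: int = DEFAULT_WINDOW,
                     baseline_points: int = DEFAULT_BASELINE_POINTS,
                     channel: str = "fluo") -> ResponseValue:
    """Normalized peak calcium response of an agonist well over its buffer well.

    max over t >= injection of [F(t)/F_baseline]_agonist / [F(t)/F_baseline]_buffer,
    after rolling-window smoothing of both wells. Ties: first occurrence.
    """
    if injection is None:
        injection = agonist_trace.injections[0]
    ag = baseline_normalize(rolling_average(agonist_trace, window), injection, baseline_points)
    bf = baseline_normalize(rolling_average(buffer_trace, window), injection, baseline_points)
    ratio = vehicle_ratio(ag, bf).channel(channel)
    post = agonist_trace.times >= injection
    value = float(np.max(ratio[post]))
    return ResponseValue(
        agonist_trace.well_id, "ca_peak", value,
        _window_params(window=window, baseline_points=baseline_points, injection=injection),
    )


def bret_ratio(trace: KineticTrace) -> KineticTrace:
    """Acceptor/donor emission ratio em540(t)/em470(t) as a single channel."""
    em540 = trace.channel("em540")
    em470 = trace.channel("em470")
    if np.any(em470 <= 0):
        raise ValueError(f"{trace.well_id}: nonpositive donor (em470) values")
    return KineticTrace(trace.well_id, trace.times.copy(),
                        {"bret": em540 / em470}, list(trace.injections))


def _normalized_bret(trace: KineticTrace, injection: float, window: int,
                     baseline_points: int) -> KineticTrace:
    ratio = bret_ratio(trace)
    smoothed = rolling_average(ratio, window)
    return baseline_normalize(smoothed, injection, baseline_points)


def _bret_area(agonist_trace: KineticTrace, buffer_trace: KineticTrace,
               injection: float | None, horizon: float, window: int,
               baseline_points: int, sign: float, assay: str,
               subtract_baseline: bool = True) -> ResponseValue:
    if injection is None:
        injection = agonist_trace.injections[0]
    ag = _normalized_bret(agonist_trace, injection, window, baseline_points)
    bf = _normalized_bret(buffer_trace, injection, window, baseline_points)
    ratio = vehicle_ratio(ag, bf).channel("bret")
    t = ag.times
    t_end = injection + horizon
    if t_end > t[-1] + 1e-9:
        warnings.warn(
            f"{agonist_trace.well_id}: horizon {horizon}s exceeds trace end; truncating",
            stacklevel=3,
        )
        t_end = t[-1]
    mask = (t >= injection) & (t <= t_end + 1e-9)
    integrand = sign * (ratio[mask] - 1.0) if subtract_baseline else sign * ratio[mask]
    value = float(np.trapezoid(integrand, t[mask]))
    return ResponseValue(
        agonist_trace.well_id, assay, value,
        _window_params(window=window, baseline_points=baseline_points,
                       injection=injection, horizon=horizon,
                       subtract_baseline=subtract_baseline),
    )


def bret_auc_response(agonist_trace: KineticTrace, buffer_trace: KineticTrace,
                      injection: float | None = None, horizon: float = DEFAULT_HORIZON,
                      window: int = DEFAULT_WINDOW,
                      baseline_points: int = DEFAULT_BASELINE_POINTS,
                      subtract_baseline: bool = True) -> ResponseValue:
    """Area under the normalized BRET ratio after injection (arrestin recruitment).

    The agonist-well ratio is normalized to its pre-injection value, divided by
    the buffer well processed identically, then integrated (trapezoid) over
    [injection, injection + horizon]. By default unity is subtracted before
    integration so buffer wells score exactly 0; set ``subtract_baseline=False``
    for the raw-area variant.
    """
    return _bret_area(agonist_trace, buffer_trace, injection, horizon, window,
                      baseline_points, sign=+1.0, assay="arr_bret_auc",
                      subtract_baseline=subtract_baseline)


def g_dissoc_aoc(agonist_trace: KineticTrace, buffer_trace: KineticTrace,
                 injection: float | None = None, horizon: float = DEFAULT_HORIZON,
                 window: int = DEFAULT_WINDOW,
                 baseline_points: int = DEFAULT_BASELINE_POINTS) -> ResponseValue:
    """Area over the curve of the normalized BRET ratio (G-protein dissociation).

    The ratio falls on stimulation; the AOC integrates (1 - normalized ratio)
    so dissociation yields positive values and buffer wells score 0.
    """
    return _bret_area(agonist_trace, buffer_trace, injection, horizon, window,
                      baseline_points, sign=-1.0, assay="g_dissoc_aoc")


def antagonist_response(trace: KineticTrace, buffer_trace: KineticTrace,
                        window: int = DEFAULT_WINDOW,
                        baseline_points: int = DEFAULT_BASELINE_POINTS,
                        channel: str = "fluo",
                        probe_conc_label: str | None = None) -> ResponseValue:
    """Peak response to the second (probe) injection in antagonist mode.

    The well receives a pretreatment at the first injection and the agonist
    probe at the second; the post-second-injection segment is normalized to its
    own immediately preceding window, with vehicle normalization applied from
    the identically processed buffer well.
    """
    if len(trace.injections) < 2:
        raise ValueError(f"{trace.well_id}: antagonist mode needs 2 injections")
    second = trace.injections[1]
    ag = baseline_normalize(rolling_average(trace, window), second, baseline_points)
    bf = baseline_normalize(rolling_average(buffer_trace, window), second, baseline_points)
    ratio = vehicle_ratio(ag, bf).channel(channel)
    post = trace.times >= second
    value = float(np.max(ratio[post]))
    return ResponseValue(
        trace.well_id, "antagonist_peak", value,
        _window_params(window=window, baseline_points=baseline_points,
                       injection=second, probe=probe_conc_label),
    )
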