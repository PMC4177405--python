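"""Fluorescence decay kinetics after stimulus offset.

For each cell, responses to the preferred stimulus are averaged across
trials (5 by default); baseline mean and SD come from the pre-stimulus
window (2 s fast indicator, 1 s slow).  Only cells whose response over
the last second of the stimulus reaches 5 baseline SDs are analyzed
(the gate).  The half-decay time is then the linearly interpolated time
for the trace to fall to half its baseline-subtracted peak, referenced
from the last response peak during stimulus presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .protocol import StimulusProtocol

__all__ = [
    "KineticsResult",
    "average_trials",
    "gate_cell",
    "half_decay_time",
    "summarize_half_decay",
    "peak_normalized_transients",
]


@dataclass
class KineticsResult:
    gated_in: bool
    baseline_mean: float
    baseline_sd: float
    response_mean: float
    half_decay: float | None = None
    peak_value: float | None = None


def average_trials(
    traces: np.ndarray, min_trials: int = 5, warn_below: bool = True
) -> np.ndarray:
    """Average trial traces (rows); warns when fewer than ``min_trials``."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if warn_below and traces.shape[0] < min_trials:
        warnings.warn(
            f"averaging only {traces.shape[0]} trials (<{min_trials})", stacklevel=2
        )
    return traces.mean(axis=0)


def gate_cell(
    avg_trace: np.ndarray,
    protocol: StimulusProtocol,
    baseline_window_s: float,
    sd_factor: float = 5.0,
) -> KineticsResult:
    """Response gate on a trial-averaged trace.

    Baseline mean/SD over the pre-stimulus window; gated in iff the mean
    over the last 1 s of the stimulus reaches
    ``baseline_mean + sd_factor * baseline_sd``.  With zero baseline SD
    (noise-free input) the gate degenerates to ``response > baseline``.
    """
    avg_trace = np.asarray(avg_trace, dtype=float)
    if avg_trace.size < protocol.frames_per_trial:
        raise ConfigurationError("trace shorter than one trial")
    base = avg_trace[protocol.baseline_slice(baseline_window_s)]
    base_mean = float(base.mean())
    base_sd = float(base.std(ddof=0))
    last_1s = int(round(protocol.frame_rate))
    stim_end = protocol.frames_per_trial
    resp = float(avg_trace[stim_end - last_1s : stim_end].mean())
    if base_sd == 0:
        gated = resp > base_mean
    else:
        gated = resp >= base_mean + sd_factor * base_sd
    return KineticsResult(
        gated_in=bool(gated),
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        response_mean=resp,
    )


def half_decay_time(
    avg_trace: np.ndarray,
    protocol: StimulusProtocol,
    baseline_mean: float,
    min_peak_fraction: float = 0.5,
) -> tuple[float | None, float]:
    """Half-decay time (s) after the last response peak, by interpolation.

    ``avg_trace`` covers one trial from its start and should extend past
    stimulus offset (frames beyond ``frames_per_trial`` are the
    post-offset continuation, e.g. the next blank).  The reference is the
    *last response peak during the stimulus*: the last local maximum of
    the baseline-subtracted trace in the stimulus window whose value
    reaches ``min_peak_fraction`` of the stimulus-window maximum (the
    filter rejects sub-threshold noise blips; for a fast indicator under
    rate modulation the true decay starts at the final modulation peak,
    which can precede stimulus offset by most of a grating cycle).
    Starting at that peak, the first sample pair bracketing half the
    peak is linearly interpolated.  Returns ``(half_decay_or_None,
    peak_value)``; None when the trace never reaches half peak before
    the recording ends.
    """
    trace = np.asarray(avg_trace, dtype=float) - baseline_mean
    offset = protocol.frames_per_trial
    if trace.size < offset:
        raise ConfigurationError("trace shorter than one trial")
    stim_start = protocol.blank_frames
    seg = trace[stim_start:offset]
    seg_max = float(seg.max())
    if seg_max <= 0:
        warnings.warn("non-positive peak; half-decay undefined", stacklevel=2)
        return None, seg_max
    # last local maximum in the stimulus window above the peak filter
    peak_idx = None
    for i in range(offset - 1, stim_start - 1, -1):
        if trace[i] < min_peak_fraction * seg_max:
            continue
        left_ok = i == stim_start or trace[i] >= trace[i - 1]
        right_ok = i + 1 >= trace.size or trace[i] > trace[i + 1]
        if left_ok and right_ok:
            peak_idx = i
            break
    if peak_idx is None:
        peak_idx = stim_start + int(np.argmax(seg))
    peak = float(trace[peak_idx])
    half = 0.5 * peak
    for i in range(peak_idx, trace.size - 1):
        if trace[i] >= half >= trace[i + 1]:
            if trace[i] == trace[i + 1]:
                cross = float(i)
            else:
                cross = i + (trace[i] - half) / (trace[i] - trace[i + 1])
            return (cross - peak_idx) / protocol.frame_rate, peak
    warnings.warn("trace never reaches half peak before recording ends", stacklevel=2)
    return None, peak


def summarize_half_decay(results: dict[str, list[float | None]]) -> pd.DataFrame:
    """Per-group mean +/- sample SD of defined half-decay times.

    ``results`` maps group label to half-decay values (None entries are
    undefined estimates and are dropped).  Groups left empty after
    dropping are omitted.  SD is reported as 0.0 with ``n = 1``.
    """
    rows = []
    for group, values in results.items():
        vals = np.array([v for v in values if v is not None], dtype=float)
        if vals.size == 0:
            continue
        rows.append(
            dict(
                group=group,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n=int(vals.size),
            )
        )
    return pd.DataFrame(rows)


def peak_normalized_transients(
    traces: list[np.ndarray],
    baselines: list[float] | None = None,
) -> np.ndarray:
    """Average of baseline-subtracted, peak-normalized transients.

    Each trace is reduced to ``(trace - baseline) / peak``; traces whose
    peak is not positive are skipped with a warning.  Normalized traces
    are aligned so their maxima coincide (at the median peak index)
    before averaging, so the output peaks at exactly 1.0.
    """
    if baselines is None:
        baselines = [0.0] * len(traces)
    normed, peak_idxs = [], []
    for trace, base in zip(traces, baselines):
        x = np.asarray(trace, dtype=float) - base
        peak = x.max()
        if peak <= 0:
            warnings.warn("non-positive peak; transient skipped", stacklevel=2)
            continue
        normed.append(x / peak)
        peak_idxs.append(int(np.argmax(x)))
    if not normed:
        raise ConfigurationError("no transient with a positive peak")
    target = int(np.median(peak_idxs))
    length = min(x.size for x in normed)
    aligned = []
    for x, pk in zip(normed, peak_idxs):
        shift = target - pk
        shifted = np.full(length, np.nan)
        src = x[:length] if shift == 0 else (
            x[-shift : length - shift] if shift < 0 else x[: length - shift]
        )
        if shift >= 0:
            shifted[shift : shift + src.size] = src
        else:
            shifted[: src.size] = src
        aligned.append(shifted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.vstack(aligned), axis=0)
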