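"""Visual responsiveness, preferred direction, and population summaries.

A cell is visually responsive when (a) its trial-mean dF/F0 exceeds 0.05
in at least one stimulus period, and (b) a one-way ANOVA across the
blank and the eight direction periods rejects at p < 0.01.  ANOVA
samples are per-trial period means (one scalar per period per trial),
not per-frame values, which would inflate N and invalidate the p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, DegenerateDataError
from .protocol import StimulusProtocol

__all__ = [
    "TrialResponseTable",
    "CellClassification",
    "period_means",
    "one_way_anova",
    "classify_responsive",
    "preferred_direction",
    "mean_preferred_response",
    "response_spectrum",
    "population_summaries",
]


@dataclass
class TrialResponseTable:
    """Per-trial period means for one cell.

    ``stim_means`` is (n_directions, n_trials_per_direction): the
    time-mean dF/F0 over each grating period.  ``blank_means`` is one
    value per trial (time-mean over that trial's blank period).
    ``directions`` are the grating directions in degrees.
    """

    stim_means: np.ndarray
    blank_means: np.ndarray
    directions: np.ndarray

    @property
    def direction_means(self) -> np.ndarray:
        """Trial-mean response per direction."""
        return self.stim_means.mean(axis=1)


@dataclass
class CellClassification:
    responsive: bool
    anova_p: float
    anova_f: float
    max_period_dff: float


def period_means(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    trial_table: pd.DataFrame | None = None,
    baseline_window_s: float | None = None,
) -> TrialResponseTable:
    """Reduce per-trial dF/F0 traces to period means.

    ``dff`` is (n_trials, frames_per_trial) in the session trial order.
    Raises when trials are missing for any direction.

    When ``baseline_window_s`` is given, the blank-period sample for each
    trial is the mean over the blank frames *preceding* the F0 window.
    The F0 frames are the dF/F0 reference (dF/F0 there is ~0 by
    construction), so including them shrinks the blank group's variance
    roughly threefold relative to the stimulus groups and inflates the
    ANOVA F statistic under the null; excluding them keeps the
    responsiveness test calibrated.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if trial_table is None:
        trial_table = protocol.trial_table()
    if dff.shape[0] != len(trial_table):
        raise ConfigurationError(
            f"{dff.shape[0]} trials of dF/F for {len(trial_table)} table rows"
        )
    if dff.shape[1] != protocol.frames_per_trial:
        raise ConfigurationError(
            f"trial length {dff.shape[1]} != protocol frames {protocol.frames_per_trial}"
        )
    blank_sl = protocol.blank_slice()
    if baseline_window_s is not None:
        stop = protocol.blank_frames - int(round(baseline_window_s * protocol.frame_rate))
        if stop >= 2:
            blank_sl = slice(0, stop)
        else:
            warnings.warn(
                "baseline window covers the whole blank; blank sample uses all "
                "blank frames (ANOVA may be anticonservative)", stacklevel=2,
            )
    blank = dff[:, blank_sl].mean(axis=1)
    stim = dff[:, protocol.stim_slice()].mean(axis=1)
    dirs = protocol.directions
    n_rep = protocol.n_trials_per_direction
    stim_means = np.full((len(dirs), n_rep), np.nan)
    counts = np.zeros(len(dirs), dtype=int)
    trial_dirs = trial_table["direction"].to_numpy()
    for trial, d in enumerate(trial_dirs):
        idx = int(np.argmin(np.abs(dirs - d)))
        if counts[idx] >= n_rep:
            raise ConfigurationError(f"too many trials for direction {d}")
        stim_means[idx, counts[idx]] = stim[trial]
        counts[idx] += 1
    if np.any(counts != n_rep):
        missing = dirs[counts != n_rep]
        raise ConfigurationError(f"missing trials for directions {missing}")
    return TrialResponseTable(stim_means=stim_means, blank_means=blank, directions=dirs)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    Returns ``(F, p)`` with p from the F distribution with
    ``(k - 1, N - k)`` degrees of freedom.  Zero within-group variance
    with unequal group means maps to ``p = 0``; fully constant data is a
    degenerate-data error.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DegenerateDataError("need >= 2 groups with >= 2 samples each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all values identical; ANOVA undefined")
    grand = allv.mean()
    n = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between = len(groups) - 1
    df_within = int(n.sum()) - len(groups)
    if ss_within == 0:
        return np.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f, df_between, df_within))
    return float(f), p


def classify_responsive(
    table: TrialResponseTable,
    alpha: float = 0.01,
    dff_threshold: float = 0.05,
) -> CellClassification:
    """Apply the two-part responsiveness criterion to one cell.

    Responsive iff the maximum trial-mean direction response exceeds
    ``dff_threshold`` AND the one-way ANOVA across the blank group plus
    one group per direction rejects at ``alpha``.  Degenerate ANOVA
    input yields non-responsive with a warning.
    """
    max_period = float(table.direction_means.max())
    groups = [table.blank_means] + [table.stim_means[i] for i in range(len(table.directions))]
    try:
        f, p = one_way_anova(groups)
    except DegenerateDataError:
        warnings.warn("degenerate ANOVA input; cell classified non-responsive",
                      stacklevel=2)
        return CellClassification(False, np.nan, np.nan, max_period)
    responsive = (max_period > dff_threshold) and (p < alpha)
    return CellClassification(responsive, p, f, max_period)


def preferred_direction(table: TrialResponseTable) -> float:
    """Direction (deg) with maximal trial-mean response; ties break to the
    lowest direction index."""
    return float(table.directions[int(np.argmax(table.direction_means))])


def moving_average(x: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average with edge shrinkage (display smoothing)."""
    kernel = np.ones(width) / width
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def mean_preferred_response(
    traces: list[np.ndarray],
    protocol: StimulusProtocol,
    min_peak: float = 1.0,
    anchors_s: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0),
    smooth: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Maxima-aligned average of large preferred-stimulus responses.

    ``traces`` are trial-averaged full-trial dF/F0 traces (one per cell).
    Cells whose peak stimulus-window dF/F0 exceeds ``min_peak`` are
    shifted by an integer number of frames so their maximum lands on the
    nearest anchor time (measured from grating onset), then averaged;
    shifted-out samples are dropped (NaN-averaged) rather than wrapped.
    Returns ``(raw_average, smoothed_average)``; the smoothed version is
    display output through a centered ``smooth``-sample moving average.
    """
    fs = protocol.frame_rate
    onset = protocol.blank_frames
    stim = protocol.stim_slice()
    anchor_frames = onset + np.round(np.array(anchors_s) * fs).astype(int)
    aligned = []
    for trace in traces:
        trace = np.asarray(trace, dtype=float)
        stim_seg = trace[stim]
        if stim_seg.max() <= min_peak:
            continue
        peak_frame = onset + int(np.argmax(stim_seg))
        anchor = anchor_frames[int(np.argmin(np.abs(anchor_frames - peak_frame)))]
        shift = int(anchor - peak_frame)
        shifted = np.full_like(trace, np.nan)
        if shift >= 0:
            shifted[shift:] = trace[: trace.size - shift] if shift else trace
        else:
            shifted[:shift] = trace[-shift:]
        aligned.append(shifted)
    if not aligned:
        raise DegenerateDataError(f"no cell exceeds peak dF/F0 {min_peak}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.vstack(aligned), axis=0)
    return avg, moving_average(avg, smooth)


def response_spectrum(
    traces: np.ndarray,
    protocol: StimulusProtocol,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Median one-sided amplitude spectrum of stimulus-window responses.

    ``traces`` is (n_cells, stim_frames): each cell's trial-averaged
    dF/F0 over the grating window.  Each trace is mean-subtracted and
    transformed with no zero padding, so the frequency resolution is
    ``1 / stim_duration``.  Amplitudes are energy-preserving (Parseval:
    the sum of squared amplitudes equals the signal's sum of squares).
    Returns ``(frequencies, median_amplitude, peak_frequency)`` with the
    peak taken over non-DC bins of the median spectrum.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[1]
    if protocol.stim_duration * protocol.temporal_frequency < 2:
        raise ConfigurationError(
            "stimulus window shorter than 2 grating cycles; spectrum unresolved"
        )
    x = traces - traces.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    weights = np.full(spec.shape[1], 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    amps = np.abs(spec) * np.sqrt(weights / n)
    freqs = np.fft.rfftfreq(n, d=1.0 / protocol.frame_rate)
    median = np.median(amps, axis=0)
    peak_freq = float(freqs[1:][int(np.argmax(median[1:]))])
    return freqs, median, peak_freq


def population_summaries(
    results: pd.DataFrame,
    dff_bins: np.ndarray | None = None,
) -> dict:
    """Across-FOV responsive fraction and peak-dF/F0 distribution.

    ``results`` needs columns ``fov``, ``excluded``, ``responsive``, and
    ``peak_dff``.  The responsive fraction is computed per FOV over
    non-excluded cells and summarized as mean +/- sample SD (ddof=1)
    across FOVs; FOVs with no analyzable cells are dropped with a
    warning.  The dF/F0 histogram covers responsive cells only.
    """
    fracs = []
    for fov, grp in results.groupby("fov"):
        ok = grp[~grp["excluded"]]
        if len(ok) == 0:
            warnings.warn(f"FOV {fov!r} has no analyzable cells; dropped", stacklevel=2)
            continue
        fracs.append(ok["responsive"].mean())
    fracs = np.array(fracs, dtype=float)
    if fracs.size == 0:
        raise DegenerateDataError("no FOV with analyzable cells")
    mean = float(fracs.mean())
    sd = float(fracs.std(ddof=1)) if fracs.size > 1 else 0.0
    resp = results[(~results["excluded"]) & results["responsive"]]
    peaks = resp["peak_dff"].to_numpy(dtype=float)
    if dff_bins is None:
        dff_bins = np.arange(0.0, max(2.0, peaks.max() if peaks.size else 2.0) + 0.25, 0.25)
    hist, edges = np.histogram(peaks, bins=dff_bins)
    return {
        "fraction_responsive_mean": mean,
        "fraction_responsive_sd": sd,
        "fraction_per_fov": fracs,
        "n_fovs": int(fracs.size),
        "dff_hist_counts": hist,
        "dff_hist_edges": edges,
    }
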