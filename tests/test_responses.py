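"""Responsiveness classification, tuning, alignment, and spectra."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from popcal.errors import ConfigurationError, DegenerateDataError
from popcal.protocol import StimulusProtocol
from popcal.responses import (
    TrialResponseTable,
    classify_responsive,
    mean_preferred_response,
    one_way_anova,
    period_means,
    population_summaries,
    preferred_direction,
    response_spectrum,
)


# ----------------------------------------------------------------------
# period means
def test_zero_dff_gives_zero_period_means(protocol):
    dff = np.zeros((protocol.n_trials, protocol.frames_per_trial))
    table = period_means(dff, protocol)
    np.testing.assert_array_equal(table.stim_means, 0.0)
    np.testing.assert_array_equal(table.blank_means, 0.0)


def test_single_direction_response_isolated(protocol):
    tt = protocol.trial_table()
    dff = np.zeros((protocol.n_trials, protocol.frames_per_trial))
    target = tt.index[tt["direction"] == 90.0].to_numpy()
    dff[np.ix_(target, np.arange(protocol.frames_per_trial)[protocol.stim_slice()])] = 1.0
    table = period_means(dff, protocol, tt)
    i90 = int(np.flatnonzero(table.directions == 90.0)[0])
    np.testing.assert_array_equal(table.stim_means[i90], 1.0)
    others = np.delete(table.stim_means, i90, axis=0)
    np.testing.assert_array_equal(others, 0.0)


def test_missing_trials_rejected(protocol):
    dff = np.zeros((protocol.n_trials - 1, protocol.frames_per_trial))
    with pytest.raises(ConfigurationError):
        period_means(dff, protocol)


# ----------------------------------------------------------------------
# ANOVA
def test_anova_matches_brute_force_sum_of_squares():
    groups = [np.array([1.2, 2.1, 1.7]), np.array([2.4, 2.2, 3.0]),
              np.array([0.5, 1.1, 0.9, 1.3])]
    f, p = one_way_anova(groups)
    # brute force from the definition
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), len(allv)
    f_ref = (ssb / (k - 1)) / (ssw / (n - k))
    assert f == pytest.approx(f_ref, abs=1e-12)
    # independent oracle
    f_sp, p_sp = scipy.stats.f_oneway(*groups)
    assert f == pytest.approx(f_sp, rel=1e-12)
    assert p == pytest.approx(p_sp, rel=1e-12)


def test_anova_identical_group_distributions_large_p():
    f, p = one_way_anova([np.array([1.0, 2.0])] * 3)
    assert p > 0.5


def test_anova_zero_within_variance_convention():
    f, p = one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
    assert p == 0.0 and np.isinf(f)


def test_anova_degenerate_input_raises():
    with pytest.raises(DegenerateDataError):
        one_way_anova([np.array([3.0, 3.0]), np.array([3.0, 3.0])])
    with pytest.raises(DegenerateDataError):
        one_way_anova([np.array([1.0])])


# ----------------------------------------------------------------------
# classification
def make_table(stim_means, blank_means, n_dirs=8):
    return TrialResponseTable(
        stim_means=np.asarray(stim_means, dtype=float),
        blank_means=np.asarray(blank_means, dtype=float),
        directions=np.arange(n_dirs) * 45.0,
    )


def test_subthreshold_response_never_responsive():
    """Max period dF/F0 of 0.04 fails the 0.05 threshold regardless of p."""
    rng = np.random.default_rng(0)
    stim = np.full((8, 5), 0.0) + rng.normal(0, 1e-4, (8, 5))
    stim[3] = 0.04  # strong separation, tiny amplitude
    table = make_table(stim, rng.normal(0, 1e-4, 40))
    cls = classify_responsive(table)
    assert cls.anova_p < 0.01 and not cls.responsive


def test_constant_dff_not_responsive():
    table = make_table(np.zeros((8, 5)), np.zeros(40))
    with pytest.warns(UserWarning):
        cls = classify_responsive(table)
    assert not cls.responsive


def test_strong_selective_response_is_responsive():
    rng = np.random.default_rng(1)
    stim = rng.normal(0, 0.005, (8, 5))
    stim[2] += 0.5
    table = make_table(stim, rng.normal(0, 0.005, 40))
    cls = classify_responsive(table)
    assert cls.responsive and cls.max_period_dff > 0.4


def test_responsiveness_monotone_in_response_scale():
    """Scaling all stimulus responses of a responsive cell up never flips
    it to non-responsive."""
    rng = np.random.default_rng(3)
    stim = rng.normal(0, 0.01, (8, 5))
    stim[5] += 0.2
    blank = rng.normal(0, 0.01, 40)
    base = classify_responsive(make_table(stim, blank))
    assert base.responsive
    for c in (1.5, 3.0, 10.0):
        scaled = classify_responsive(make_table(c * stim, blank))
        assert scaled.responsive


def test_preferred_direction_argmax_and_tie_break():
    stim = np.zeros((8, 5))
    stim[4] = 1.0
    assert preferred_direction(make_table(stim, np.zeros(40))) == 180.0
    tie = np.zeros((8, 5))
    tie[2] = tie[6] = 1.0  # exact two-way tie -> lower index wins
    assert preferred_direction(make_table(tie, np.zeros(40))) == 90.0


# ----------------------------------------------------------------------
# alignment and averaging
def test_alignment_zero_shift_when_peak_on_anchor(protocol):
    trace = np.zeros(protocol.frames_per_trial)
    peak_frame = protocol.blank_frames + int(2.0 * protocol.frame_rate)
    trace[peak_frame] = 2.0
    avg, smoothed = mean_preferred_response([trace], protocol)
    assert int(np.nanargmax(avg)) == peak_frame


def test_alignment_snaps_to_nearest_anchor(protocol):
    trace = np.zeros(protocol.frames_per_trial)
    peak_frame = protocol.blank_frames + int(round(2.4 * protocol.frame_rate))
    trace[peak_frame] = 2.0
    avg, _ = mean_preferred_response([trace], protocol)
    anchor_frame = protocol.blank_frames + int(2.0 * protocol.frame_rate)
    assert int(np.nanargmax(avg)) == anchor_frame


def test_averaging_identical_traces_is_idempotent(protocol):
    trace = np.zeros(protocol.frames_per_trial)
    trace[protocol.blank_frames + 15] = 3.0
    avg, _ = mean_preferred_response([trace.copy() for _ in range(5)], protocol)
    np.testing.assert_allclose(avg, trace)


def test_no_qualifying_cells_raises(protocol):
    small = np.full(protocol.frames_per_trial, 0.5)  # peak below 1.0
    with pytest.raises(DegenerateDataError):
        mean_preferred_response([small], protocol)


# ----------------------------------------------------------------------
# spectrum
def test_pure_tone_peaks_at_grating_frequency(protocol):
    t = np.arange(protocol.stim_frames) / protocol.frame_rate
    trace = np.sin(2 * np.pi * 1.0 * t)
    freqs, med, peak = response_spectrum(trace[None, :], protocol)
    assert peak == pytest.approx(1.0)
    assert freqs[1] == pytest.approx(0.25)  # 1 / stim_duration resolution


def test_constant_trace_has_no_nondc_power(protocol):
    freqs, med, _ = response_spectrum(np.full((1, 60), 5.0), protocol)
    np.testing.assert_allclose(med[1:], 0.0, atol=1e-12)


def test_spectrum_parseval_consistency(protocol):
    rng = np.random.default_rng(8)
    traces = rng.standard_normal((7, protocol.stim_frames))
    freqs, med, _ = response_spectrum(traces, protocol)
    # check on a single trace (median across one cell is that cell)
    x = traces[:1] - traces[:1].mean()
    _, amps, _ = response_spectrum(traces[:1], protocol)
    assert np.sum(amps**2) == pytest.approx(np.sum(x**2), rel=1e-6)


def test_too_short_window_rejected():
    p = StimulusProtocol(stim_duration=1.0, blank_duration=1.0)
    with pytest.raises(ConfigurationError):
        response_spectrum(np.zeros((1, p.stim_frames)), p)


# ----------------------------------------------------------------------
# population summaries
def test_population_summary_hand_computed():
    df = pd.DataFrame({
        "fov": [0] * 5 + [1] * 5,
        "excluded": [False] * 10,
        "responsive": [True, False, False, False, False,  # 0.2
                       True, True, False, False, False],  # 0.4
        "peak_dff": [1.0] * 10,
    })
    s = population_summaries(df)
    assert s["fraction_responsive_mean"] == pytest.approx(0.3)
    assert s["fraction_responsive_sd"] == pytest.approx(np.sqrt(0.02), rel=1e-12)


def test_all_responsive_identical_fovs():
    df = pd.DataFrame({
        "fov": [0, 0, 1, 1],
        "excluded": [False] * 4,
        "responsive": [True] * 4,
        "peak_dff": [1.5] * 4,
    })
    s = population_summaries(df)
    assert s["fraction_responsive_mean"] == 1.0
    assert s["fraction_responsive_sd"] == 0.0


def test_empty_fov_dropped_with_warning():
    df = pd.DataFrame({
        "fov": [0, 0, 1],
        "excluded": [False, False, True],
        "responsive": [True, False, False],
        "peak_dff": [1.0, np.nan, np.nan],
    })
    with pytest.warns(UserWarning):
        s = population_summaries(df)
    assert s["n_fovs"] == 1
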