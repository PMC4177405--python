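"""Stimulus protocol: timing of the drifting-grating experiment.

A session is a sequence of trials; each trial is a blank (uniform gray)
period followed by a drifting sinusoidal grating moving in one of
``n_directions`` equally spaced directions.  Defaults reproduce a standard
visual-cortex mapping protocol: 4 s blank, 4 s grating at 1 Hz temporal
frequency, 8 directions, imaged at 15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["StimulusProtocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and geometry of a blank/grating trial structure.

    Parameters
    ----------
    blank_duration, stim_duration
        Durations in seconds of the blank and grating periods of one trial.
    n_directions
        Number of equally spaced grating drift directions.
    temporal_frequency
        Drift frequency of the grating in Hz.
    spatial_frequency
        Grating spatial frequency in cycles/degree (metadata only; no
        spatial receptive fields are modelled).
    frame_rate
        Imaging frame rate in Hz.  ``frame_rate * (blank + stim)`` must be
        an integer so trials align to frames.
    n_trials_per_direction
        Repetitions of each direction in a session.
    """

    blank_duration: float = 4.0
    stim_duration: float = 4.0
    n_directions: int = 8
    temporal_frequency: float = 1.0
    spatial_frequency: float = 0.05
    frame_rate: float = 15.0
    n_trials_per_direction: int = 5

    def __post_init__(self) -> None:
        if self.blank_duration <= 0 or self.stim_duration <= 0:
            raise ConfigurationError("blank and stimulus durations must be > 0")
        if self.n_directions < 1:
            raise ConfigurationError("n_directions must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.n_trials_per_direction < 1:
            raise ConfigurationError("n_trials_per_direction must be >= 1")
        n = self.frame_rate * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"frame_rate * trial_duration = {n} is not an integer frame count"
            )

    # ------------------------------------------------------------------
    # derived timing
    @property
    def trial_duration(self) -> float:
        return self.blank_duration + self.stim_duration

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.frame_rate * self.trial_duration))

    @property
    def blank_frames(self) -> int:
        return int(round(self.frame_rate * self.blank_duration))

    @property
    def stim_frames(self) -> int:
        return self.frames_per_trial - self.blank_frames

    @property
    def n_trials(self) -> int:
        return self.n_directions * self.n_trials_per_direction

    @property
    def session_frames(self) -> int:
        return self.n_trials * self.frames_per_trial

    @property
    def directions(self) -> np.ndarray:
        """Grating directions in degrees, ``[0, 360)``."""
        return np.arange(self.n_directions) * 360.0 / self.n_directions

    def frame_times(self, n_frames: int | None = None) -> np.ndarray:
        """Start times (s) of the first ``n_frames`` frames of a trial."""
        if n_frames is None:
            n_frames = self.frames_per_trial
        return np.arange(n_frames) / self.frame_rate

    def stim_slice(self) -> slice:
        """Frame slice of the grating period within one trial."""
        return slice(self.blank_frames, self.frames_per_trial)

    def blank_slice(self) -> slice:
        return slice(0, self.blank_frames)

    def baseline_slice(self, window_s: float) -> slice:
        """Frames whose start times fall in ``[onset - window, onset)``.

        This is the pre-stimulus window used for F0 estimation; it must fit
        inside the blank period.
        """
        if window_s <= 0 or window_s > self.blank_duration + 1e-9:
            raise ConfigurationError(
                f"baseline window {window_s} s does not fit in the "
                f"{self.blank_duration} s blank period"
            )
        n = int(round(window_s * self.frame_rate))
        return slice(self.blank_frames - n, self.blank_frames)

    # ------------------------------------------------------------------
    # trial bookkeeping
    def trial_table(self) -> pd.DataFrame:
        """Session trial table: one row per trial, repetition-major order.

        Columns: trial, rep, direction (deg), blank_start, stim_start,
        stim_end (seconds from session start).
        """
        rows = []
        t = 0.0
        trial = 0
        for rep in range(self.n_trials_per_direction):
            for d in self.directions:
                rows.append(
                    dict(
                        trial=trial,
                        rep=rep,
                        direction=float(d),
                        blank_start=t,
                        stim_start=t + self.blank_duration,
                        stim_end=t + self.trial_duration,
                    )
                )
                t += self.trial_duration
                trial += 1
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown protocol keys: {sorted(unknown)}")
        return cls(**d)
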