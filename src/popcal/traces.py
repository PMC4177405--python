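"""Neuropil correction, baseline exclusion filtering, and dF/F0.

The measured somatic signal mixes cytosolic fluorescence with
out-of-focus neuropil; the correction subtracts a fixed fraction r of
the surrounding neuropil trace:

    F_corrected(t) = F_measured(t) - r * F_neuropil(t),   r = 0.7 default.

Cells whose pre-stimulus baseline is not brighter than the neuropil by
more than a margin (3% default) are excluded: their F0 cannot be
estimated reliably after subtraction.  The comparison uses uncorrected
baseline means, then the correction is applied to the kept cells.

F0 is the mean of the corrected trace over a pre-stimulus window ending
at grating onset — 2 s for the fast indicator, 1 s for the slow one —
and dF/F0 = (F - F0) / F0 per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError
from .protocol import StimulusProtocol

__all__ = [
    "CorrectionConfig",
    "CellTraces",
    "neuropil_correct",
    "exclusion_filter",
    "compute_dff",
    "process_cell",
]

#: Pre-stimulus F0 window per indicator speed (seconds).  The fast
#: indicator uses a longer window because its transients decay quickly,
#: leaving more of the blank period at rest.
BASELINE_WINDOWS_S = {"fast": 2.0, "slow": 1.0}


@dataclass(frozen=True)
class CorrectionConfig:
    """Neuropil-correction and exclusion settings.

    ``r`` is a single global contamination ratio (0.7 default; may need
    adjustment per preparation, so it is exposed).  ``exclusion_margin``
    is the fractional baseline-over-neuropil excess required to keep a
    cell.  ``baseline_window_s`` is the F0 window; when ``None`` it is
    looked up from the indicator speed.
    """

    r: float = 0.7
    exclusion_margin: float = 0.03
    indicator: str = "fast"
    baseline_window_s: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ConfigurationError("r must be in [0, 1]")
        if self.exclusion_margin < 0:
            raise ConfigurationError("exclusion_margin must be >= 0")
        if self.baseline_window_s is None and self.indicator not in BASELINE_WINDOWS_S:
            raise ConfigurationError(
                f"indicator must be one of {sorted(BASELINE_WINDOWS_S)} "
                "when baseline_window_s is not given"
            )

    @property
    def window_s(self) -> float:
        if self.baseline_window_s is not None:
            return self.baseline_window_s
        return BASELINE_WINDOWS_S[self.indicator]


@dataclass
class CellTraces:
    """Per-cell trace bundle through the processing chain.

    Arrays are (n_trials, frames_per_trial); ``f0`` is per trial.
    Excluded cells carry a reason and must be dropped from all
    downstream statistics.
    """

    raw: np.ndarray
    neuropil: np.ndarray
    corrected: np.ndarray | None
    f0: np.ndarray | None
    dff: np.ndarray | None
    excluded: bool = False
    exclusion_reason: str | None = None


def neuropil_correct(raw: np.ndarray, neuropil: np.ndarray, r: float = 0.7) -> np.ndarray:
    """Elementwise ``raw - r * neuropil``; identity at r = 0."""
    raw = np.asarray(raw, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if raw.shape != neuropil.shape:
        raise ShapeError(f"raw {raw.shape} and neuropil {neuropil.shape} differ")
    return raw - r * neuropil


def exclusion_filter(
    raw: np.ndarray,
    neuropil: np.ndarray,
    protocol: StimulusProtocol,
    baseline_window_s: float,
    margin: float = 0.03,
) -> bool:
    """Keep/exclude decision on uncorrected baseline means.

    ``raw`` and ``neuropil`` are (n_trials, frames_per_trial).  The cell
    is kept iff its mean raw fluorescence over the pre-stimulus baseline
    window (pooled across trials) exceeds ``(1 + margin)`` times the
    neuropil mean over the same window.  Returns True to keep.
    """
    raw = np.atleast_2d(raw)
    neuropil = np.atleast_2d(neuropil)
    if raw.shape != neuropil.shape:
        raise ShapeError(f"raw {raw.shape} and neuropil {neuropil.shape} differ")
    sl = protocol.baseline_slice(baseline_window_s)
    raw_base = float(raw[:, sl].mean())
    np_base = float(neuropil[:, sl].mean())
    if np_base <= 0:
        warnings.warn(
            "non-positive neuropil baseline; keep/exclude decided on raw means",
            stacklevel=2,
        )
    return raw_base > (1.0 + margin) * np_base


def compute_dff(
    corrected: np.ndarray,
    protocol: StimulusProtocol,
    baseline_window_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial dF/F0 of corrected traces.

    ``corrected`` is (n_trials, frames_per_trial).  F0 is the mean over
    the frames whose start times fall in ``[onset - window, onset)`` of
    each trial; ``dff = (corrected - F0) / F0``.  Returns ``(dff, f0)``;
    the caller must treat any ``f0 <= 0`` as an exclusion (unreliable
    baseline).
    """
    corrected = np.atleast_2d(np.asarray(corrected, dtype=float))
    sl = protocol.baseline_slice(baseline_window_s)
    f0 = corrected[:, sl].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (corrected - f0[:, None]) / f0[:, None]
    return dff, f0


def process_cell(
    raw: np.ndarray,
    neuropil: np.ndarray,
    protocol: StimulusProtocol,
    config: CorrectionConfig,
) -> CellTraces:
    """Exclusion filter -> neuropil correction -> dF/F0 for one cell.

    The baseline-vs-neuropil comparison precedes correction (excluded
    cells are never corrected); cells whose corrected F0 is non-positive
    in any trial are also excluded.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    neuropil = np.atleast_2d(np.asarray(neuropil, dtype=float))
    keep = exclusion_filter(raw, neuropil, protocol, config.window_s, config.exclusion_margin)
    if not keep:
        return CellTraces(
            raw=raw, neuropil=neuropil, corrected=None, f0=None, dff=None,
            excluded=True, exclusion_reason="baseline within margin of neuropil",
        )
    corrected = neuropil_correct(raw, neuropil, config.r)
    dff, f0 = compute_dff(corrected, protocol, config.window_s)
    if np.any(f0 <= 0):
        return CellTraces(
            raw=raw, neuropil=neuropil, corrected=corrected, f0=f0, dff=None,
            excluded=True, exclusion_reason="non-positive F0 after correction",
        )
    return CellTraces(
        raw=raw, neuropil=neuropil, corrected=corrected, f0=f0, dff=dff, excluded=False
    )
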