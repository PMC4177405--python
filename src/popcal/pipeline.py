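"""Orchestration: measured traces -> per-cell results -> summaries.

The stage order mirrors the analysis the package implements: extract
(or simulate) raw and neuropil traces, apply the baseline exclusion
filter, neuropil-correct the kept cells, compute per-trial dF/F0,
classify responsiveness, then run tuning/kinetics/spectral summaries on
the responsive cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import responses as resp
from .io import RunConfig, write_traces
from .models import SceneModel, indicator_preset
from .protocol import StimulusProtocol
from .synthetic import make_population_tuning, simulate_population
from .traces import CorrectionConfig, process_cell

logger = logging.getLogger("popcal")

__all__ = ["SessionResults", "analyze_session", "kinetics_analysis", "pipeline_run"]


@dataclass
class SessionResults:
    """Per-cell classification plus the traces needed downstream."""

    protocol: StimulusProtocol
    config: CorrectionConfig
    results: pd.DataFrame  # cell, fov, excluded, responsive, anova_p, ...
    dff: list[np.ndarray | None]  # per cell (n_trials, frames) or None
    corrected: list[np.ndarray | None]  # per cell session-long trace or None
    f0: list[np.ndarray | None]  # per cell per-trial F0
    trial_table: pd.DataFrame

    def preferred_trials(self, cell: int) -> np.ndarray:
        """Trial indices of the cell's preferred direction."""
        pref = self.results.loc[cell, "preferred_direction"]
        return np.flatnonzero(self.trial_table["direction"].to_numpy() == pref)

    def preferred_trace(self, cell: int) -> np.ndarray:
        """Trial-averaged dF/F0 at the preferred direction (full trial)."""
        d = self.dff[cell]
        if d is None:
            raise ValueError(f"cell {cell} is excluded")
        return d[self.preferred_trials(cell)].mean(axis=0)

    def extended_preferred_trace(self, cell: int, tail_frames: int) -> np.ndarray:
        """Preferred-direction average extended ``tail_frames`` past offset.

        The tail comes from the next trial's blank on the session clock,
        so the post-stimulus decay is observable; preferred trials
        lacking a full tail (end of session) are dropped from the
        average.
        """
        trace = self.corrected[cell]
        f0 = self.f0[cell]
        if trace is None or f0 is None:
            raise ValueError(f"cell {cell} is excluded")
        f = self.protocol.frames_per_trial
        segs = []
        for t in self.preferred_trials(cell):
            start, stop = t * f, t * f + f + tail_frames
            if stop <= trace.size:
                segs.append((trace[start:stop] - f0[t]) / f0[t])
        if not segs:
            raise ValueError(f"cell {cell}: no preferred trial with a full tail")
        return np.mean(segs, axis=0)


def analyze_session(
    measured: np.ndarray,
    measured_neuropil: np.ndarray,
    protocol: StimulusProtocol,
    config: CorrectionConfig,
    fov: str | int = 0,
    trial_table: pd.DataFrame | None = None,
) -> SessionResults:
    """Run exclusion -> correction -> dF/F0 -> classification per cell.

    ``measured`` and ``measured_neuropil`` are (n_cells, session_frames)
    or (n_cells, n_trials, frames_per_trial).
    """
    measured = np.asarray(measured, dtype=float)
    measured_neuropil = np.asarray(measured_neuropil, dtype=float)
    f = protocol.frames_per_trial
    if measured.ndim == 2:
        n_cells = measured.shape[0]
        per_trial = measured.reshape(n_cells, -1, f)
        np_per_trial = measured_neuropil.reshape(n_cells, -1, f)
        session = measured
    else:
        n_cells = measured.shape[0]
        per_trial = measured
        np_per_trial = measured_neuropil
        session = measured.reshape(n_cells, -1)
    if trial_table is None:
        trial_table = protocol.trial_table()

    rows = []
    dffs: list[np.ndarray | None] = []
    correcteds: list[np.ndarray | None] = []
    f0s: list[np.ndarray | None] = []
    for i in range(n_cells):
        cell = process_cell(per_trial[i], np_per_trial[i], protocol, config)
        if cell.excluded:
            rows.append(
                dict(cell=i, fov=fov, excluded=True, responsive=False,
                     anova_p=np.nan, max_period_dff=np.nan,
                     preferred_direction=np.nan, peak_dff=np.nan,
                     exclusion_reason=cell.exclusion_reason)
            )
            dffs.append(None)
            correcteds.append(None)
            f0s.append(None)
            continue
        table = resp.period_means(cell.dff, protocol, trial_table,
                                  baseline_window_s=config.window_s)
        cls = resp.classify_responsive(table)
        pref = resp.preferred_direction(table)
        pref_trials = np.flatnonzero(trial_table["direction"].to_numpy() == pref)
        pref_avg = cell.dff[pref_trials].mean(axis=0)
        peak_dff = float(pref_avg[protocol.stim_slice()].max())
        rows.append(
            dict(cell=i, fov=fov, excluded=False, responsive=cls.responsive,
                 anova_p=cls.anova_p, max_period_dff=cls.max_period_dff,
                 preferred_direction=pref, peak_dff=peak_dff,
                 exclusion_reason=None)
        )
        dffs.append(cell.dff)
        correcteds.append(cell.corrected.reshape(-1))
        f0s.append(cell.f0)
    results = pd.DataFrame(rows).set_index("cell", drop=False)
    logger.info(
        "analyzed %d cells: %d excluded, %d responsive",
        n_cells, int(results["excluded"].sum()), int(results["responsive"].sum()),
    )
    return SessionResults(
        protocol=protocol, config=config, results=results, dff=dffs,
        corrected=correcteds, f0=f0s, trial_table=trial_table,
    )


def kinetics_analysis(
    session: SessionResults,
    sd_factor: float = 5.0,
    tail_s: float | None = None,
) -> pd.DataFrame:
    """Gate responsive cells and estimate half-decay after stimulus offset.

    Returns one row per responsive cell: gated_in flag, baseline stats,
    and half-decay seconds (NaN when the gate fails or the trace never
    reaches half peak).
    """
    protocol = session.protocol
    if tail_s is None:
        tail_s = protocol.blank_duration
    tail_frames = int(round(tail_s * protocol.frame_rate))
    rows = []
    for i in session.results.index[session.results["responsive"]]:
        try:
            trace = session.extended_preferred_trace(int(i), tail_frames)
        except ValueError:
            continue
        gate = kin.gate_cell(trace, protocol, session.config.window_s, sd_factor)
        if gate.gated_in:
            hd, peak = kin.half_decay_time(trace, protocol, gate.baseline_mean)
        else:
            hd, peak = np.nan, np.nan
        rows.append(
            dict(cell=int(i), gated_in=gate.gated_in,
                 baseline_mean=gate.baseline_mean, baseline_sd=gate.baseline_sd,
                 half_decay=np.nan if hd is None else hd, peak=peak)
        )
    df = pd.DataFrame(rows, columns=["cell", "gated_in", "baseline_mean",
                                     "baseline_sd", "half_decay", "peak"])
    logger.info("kinetics: %d responsive cells, %d gated in",
                len(df), int(df["gated_in"].sum()) if len(df) else 0)
    return df


def pipeline_run(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate one field of view and run the full analysis pipeline.

    Writes traces.h5, results.csv, kinetics.csv, summary.json, and the
    resolved config next to them.  Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.make_protocol()
    kinetics_model = indicator_preset(config.indicator)
    scene = SceneModel(n_cells=config.n_cells, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    tuning = make_population_tuning(
        config.n_cells, protocol, tuned_fraction=config.tuned_fraction, rng=rng
    )
    sim = simulate_population(protocol, scene, tuning, kinetics_model,
                              seed=int(rng.integers(2**31)))
    corr = CorrectionConfig(
        r=config.r, exclusion_margin=config.exclusion_margin,
        indicator=config.indicator, baseline_window_s=config.baseline_window_s,
    )
    session = analyze_session(sim.measured, sim.measured_neuropil, protocol, corr)
    kdf = kinetics_analysis(session)

    results = session.results.reset_index(drop=True)
    results = results.merge(kdf[["cell", "gated_in", "half_decay"]], on="cell",
                            how="left")
    results.to_csv(out / "results.csv", index=False)
    kdf.to_csv(out / "kinetics.csv", index=False)
    write_traces(out / "traces.h5", protocol, sim.measured, sim.measured_neuropil)
    config.to_yaml(out / "config.yaml")
    summary = {
        "n_cells": int(config.n_cells),
        "n_excluded": int(results["excluded"].sum()),
        "n_responsive": int(results["responsive"].sum()),
        "n_gated": int(results["gated_in"].fillna(False).sum()),
        "half_decay_mean_s": float(np.nanmean(results["half_decay"]))
        if results["half_decay"].notna().any() else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline run complete: %s", summary)
    return out
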