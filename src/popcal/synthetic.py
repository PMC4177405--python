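"""Forward simulation of population two-photon imaging with ground truth.

The generative chain is: direction-tuned inhomogeneous-Poisson spike
trains -> single-spike calcium transients summed linearly into a
cytosolic fluorescence trace -> measured somatic signal contaminated by a
shared neuropil trace plus noise -> optionally a rendered movie (somata
drawn as nucleus-excluded rings over a smooth neuropil field).  A
two-channel histology generator produces NeuN-like (red) and
GCaMP-like (green) images plus a fluorescent-bead field for brightness
normalization.

Every stage is seeded and returns its ground truth, so downstream
analysis modules can be validated against known spike times, tuning,
kinetics, and contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import ConfigurationError, PlacementError
from .models import KineticsModel, SceneModel, TuningModel
from .protocol import StimulusProtocol

__all__ = [
    "tuning_gain",
    "firing_rate",
    "generate_spike_trains",
    "session_spike_times",
    "transient_kernel",
    "spikes_to_fluorescence",
    "compose_measurement",
    "GroundTruth",
    "PopulationSim",
    "make_population_tuning",
    "simulate_population",
    "render_movie",
    "HistologyScene",
    "generate_histology_image",
]


# ----------------------------------------------------------------------
# spike generation
def tuning_gain(direction: np.ndarray | float, tuning: TuningModel) -> np.ndarray:
    """Von Mises-shaped direction gain, normalized to 1 at the preferred.

    ``g = exp(kappa * (cos(theta - preferred) - 1))``; ``kappa = 0`` gives a
    flat gain of 1 (untuned limit).
    """
    delta = np.deg2rad(np.asarray(direction, dtype=float) - tuning.preferred_direction)
    return np.exp(tuning.tuning_width * (np.cos(delta) - 1.0))


def firing_rate(
    t: np.ndarray, direction: float, tuning: TuningModel, protocol: StimulusProtocol
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at trial times ``t`` (s).

    Baseline during the blank; during the grating the rate is
    ``baseline + (peak - baseline) * gain * (1 + m sin(2 pi f_t t'))``
    with ``t'`` measured from grating onset, clipped at zero.
    """
    t = np.asarray(t, dtype=float)
    rate = np.full_like(t, tuning.baseline_rate)
    if tuning.is_tuned and tuning.peak_rate > tuning.baseline_rate:
        in_stim = (t >= protocol.blank_duration) & (t < protocol.trial_duration)
        ts = t[in_stim] - protocol.blank_duration
        g = float(tuning_gain(direction, tuning))
        mod = 1.0 + tuning.modulation_depth * np.sin(
            2.0 * np.pi * protocol.temporal_frequency * ts
        )
        rate[in_stim] = tuning.baseline_rate + (
            tuning.peak_rate - tuning.baseline_rate
        ) * g * mod
    return np.clip(rate, 0.0, None)


def generate_spike_trains(
    tuning: TuningModel,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike times for one cell, one array per trial.

    Trials follow :meth:`StimulusProtocol.trial_table` order; times are in
    seconds relative to each trial's start.  Sampling uses thinning against
    the per-trial rate ceiling, so the expected count equals the integral
    of the rate.
    """
    if not isinstance(protocol, StimulusProtocol):
        raise ConfigurationError("protocol must be a StimulusProtocol")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = protocol.trial_table()
    trains: list[np.ndarray] = []
    for direction in table["direction"].to_numpy():
        g = float(tuning_gain(direction, tuning)) if tuning.is_tuned else 0.0
        stim_peak = tuning.baseline_rate + (
            tuning.peak_rate - tuning.baseline_rate
        ) * g * (1.0 + tuning.modulation_depth)
        lam_max = max(tuning.baseline_rate, stim_peak)
        if lam_max <= 0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(lam_max * protocol.trial_duration)
        cand = np.sort(rng.uniform(0.0, protocol.trial_duration, size=n))
        keep = rng.uniform(0.0, lam_max, size=n) < firing_rate(
            cand, direction, tuning, protocol
        )
        trains.append(cand[keep])
    return trains


def session_spike_times(
    trains: Sequence[np.ndarray], protocol: StimulusProtocol
) -> np.ndarray:
    """Concatenate per-trial spike times onto the session clock."""
    offsets = np.arange(len(trains)) * protocol.trial_duration
    if len(trains) == 0:
        return np.empty(0)
    return np.concatenate([t + off for t, off in zip(trains, offsets)])


# ----------------------------------------------------------------------
# calcium transient kernel
@lru_cache(maxsize=64)
def _calibrated_decay_tau(rise_time: float, decay_half_time: float) -> float:
    """Decay time constant of the difference-of-exponentials kernel whose
    measured post-peak half-decay equals ``decay_half_time`` exactly.

    For a kernel ``exp(-t/tau_d) - exp(-t/tau_r)`` the half-decay is close
    to but not equal to ``tau_d ln 2`` (the rise term keeps decaying after
    the peak), so ``tau_d`` is solved numerically.
    """
    tau_r = rise_time

    def half_decay_of(tau_d: float) -> float:
        t_peak = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
        peak = math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r)

        def f(s: float) -> float:
            t = t_peak + s
            return (math.exp(-t / tau_d) - math.exp(-t / tau_r)) - 0.5 * peak

        return brentq(f, 1e-9, 50.0 * tau_d, xtol=1e-12)

    target = decay_half_time
    lo = max(tau_r * 1.0001, 0.05 * target / math.log(2.0))
    hi = 10.0 * target / math.log(2.0)
    if half_decay_of(lo) > target:
        raise ConfigurationError(
            f"rise_time {tau_r} too slow for decay_half_time {target}"
        )
    return brentq(lambda td: half_decay_of(td) - target, lo, hi, xtol=1e-12)


def transient_kernel(kinetics: KineticsModel) -> Callable[[np.ndarray], np.ndarray]:
    """Single-spike transient, peak-normalized to 1, as a callable of time.

    ``k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / peak`` for ``t >= 0`` and 0
    before the spike; the post-peak half-decay equals
    ``kinetics.decay_half_time`` by construction.
    """
    tau_r = kinetics.rise_time
    tau_d = _calibrated_decay_tau(tau_r, kinetics.decay_half_time)
    t_peak = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    peak = math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r)

    def kernel(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        tp = t[pos]
        out[pos] = (np.exp(-tp / tau_d) - np.exp(-tp / tau_r)) / peak
        return out

    kernel.tau_rise = tau_r  # type: ignore[attr-defined]
    kernel.tau_decay = tau_d  # type: ignore[attr-defined]
    kernel.t_peak = t_peak  # type: ignore[attr-defined]
    return kernel


def kernel_support(kinetics: KineticsModel, rel: float = 1e-12) -> float:
    """Duration (s) after which the transient is below ``rel`` of its peak."""
    kernel = transient_kernel(kinetics)
    return kernel.t_peak + kernel.tau_decay * math.log(1.0 / rel)


def spikes_to_fluorescence(
    spikes: np.ndarray | Sequence[np.ndarray],
    kinetics: KineticsModel,
    protocol: StimulusProtocol,
    n_frames: int | None = None,
) -> np.ndarray:
    """Cytosolic fluorescence trace on the frame grid (arbitrary units).

    ``spikes`` is either a flat array of spike times on the session clock
    or a per-trial sequence (concatenated via :func:`session_spike_times`;
    transients then sum across trial boundaries).  The trace is
    ``baseline * (1 + amplitude_per_spike * sum_k kernel(t - t_k))``, so a
    single spike produces a dF/F transient peaking at
    ``amplitude_per_spike``.
    """
    if protocol.frame_rate <= 0:
        raise ConfigurationError("frame_rate must be > 0")
    if isinstance(spikes, np.ndarray) and spikes.ndim <= 1:
        times = np.asarray(spikes, dtype=float)
        if n_frames is None:
            n_frames = protocol.frames_per_trial
    else:
        times = session_spike_times(list(spikes), protocol)
        if n_frames is None:
            n_frames = len(spikes) * protocol.frames_per_trial
    base = kinetics.baseline_fluorescence
    if times.size == 0:
        return np.full(n_frames, base)
    kernel = transient_kernel(kinetics)
    fs = protocol.frame_rate
    # each transient only touches frames within its (finite) support
    support = int(math.ceil(kernel_support(kinetics) * fs)) + 1
    dff = np.zeros(n_frames)
    first = np.ceil(times * fs).astype(int)  # first frame at/after the spike
    offsets = np.arange(support)
    idx = first[:, None] + offsets[None, :]
    dt = idx / fs - times[:, None]
    valid = (idx >= 0) & (idx < n_frames)
    np.add.at(dff, idx[valid], kernel(dt[valid]))
    return base * (1.0 + kinetics.amplitude_per_spike * dff)


# ----------------------------------------------------------------------
# measurement composition
def compose_measurement(
    cytosolic: np.ndarray,
    neuropil_trace: np.ndarray,
    scene: SceneModel,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Contaminate cytosolic traces with neuropil and noise.

    Returns ``(measured, measured_neuropil)`` where
    ``measured[i] = cytosolic[i] + r_true * neuropil + noise`` and
    ``measured_neuropil[i]`` is the neuropil trace with independent
    measurement noise (what a neuropil-region extraction would see).
    With ``gaussian_noise_fraction == 0`` and no photon noise the
    composition is exact and deterministic.
    """
    cyto = np.atleast_2d(np.asarray(cytosolic, dtype=float))
    npil = np.asarray(neuropil_trace, dtype=float)
    if cyto.shape[-1] != npil.shape[-1]:
        raise ConfigurationError("cytosolic and neuropil traces must share the frame grid")
    measured = cyto + scene.contamination_ratio_true * npil[None, :]
    measured_np = np.broadcast_to(npil, cyto.shape).copy()
    if scene.photon_scaling is not None:
        rng = np.random.default_rng(scene.seed) if rng is None else rng
        s = scene.photon_scaling
        measured = rng.poisson(np.clip(measured, 0, None) * s) / s
        measured_np = rng.poisson(np.clip(measured_np, 0, None) * s) / s
    elif scene.gaussian_noise_fraction > 0:
        rng = np.random.default_rng(scene.seed) if rng is None else rng
        base = np.median(cyto, axis=-1, keepdims=True)
        measured = measured + rng.standard_normal(cyto.shape) * (
            scene.gaussian_noise_fraction * base
        )
        np_sd = scene.gaussian_noise_fraction * np.median(npil)
        measured_np = measured_np + rng.standard_normal(cyto.shape) * np_sd
    if cytosolic.ndim == 1:
        return measured[0], measured_np[0]
    return measured, measured_np


# ----------------------------------------------------------------------
# population simulation
@dataclass
class GroundTruth:
    """Everything the simulator knows: the validation reference."""

    spike_times: list[list[np.ndarray]]  # [cell][trial] -> seconds in trial
    tuning: list[TuningModel]
    kinetics: list[KineticsModel]
    cytosolic_traces: np.ndarray  # (n_cells, session_frames)
    neuropil_trace: np.ndarray  # (session_frames,)
    contamination_ratio_true: float


@dataclass
class PopulationSim:
    """One simulated session: ground truth plus measured traces."""

    protocol: StimulusProtocol
    scene: SceneModel
    truth: GroundTruth
    measured: np.ndarray  # (n_cells, session_frames)
    measured_neuropil: np.ndarray  # (n_cells, session_frames)
    trial_table: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.measured.shape[0]

    def per_trial(self, traces: np.ndarray) -> np.ndarray:
        """Reshape session-long traces to (..., n_trials, frames_per_trial)."""
        f = self.protocol.frames_per_trial
        return traces.reshape(*traces.shape[:-1], self.protocol.n_trials, f)


def make_population_tuning(
    n_cells: int,
    protocol: StimulusProtocol,
    tuned_fraction: float = 0.3,
    rng: int | np.random.Generator = 0,
    template: TuningModel | None = None,
) -> list[TuningModel]:
    """Assign tuning models to a population.

    Each cell is tuned with probability ``tuned_fraction``; tuned cells
    get a preferred direction drawn uniformly from the protocol's
    stimulus directions and the template's rates; untuned cells fire at
    the template's baseline rate only.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    template = template or TuningModel()
    out = []
    for _ in range(n_cells):
        if rng.uniform() < tuned_fraction:
            pref = float(rng.choice(protocol.directions))
            out.append(
                TuningModel(
                    preferred_direction=pref,
                    tuning_width=template.tuning_width,
                    baseline_rate=template.baseline_rate,
                    peak_rate=template.peak_rate,
                    modulation_depth=template.modulation_depth,
                    is_tuned=True,
                )
            )
        else:
            out.append(template.untuned())
    return out


def simulate_population(
    protocol: StimulusProtocol,
    scene: SceneModel,
    tuning: Sequence[TuningModel],
    kinetics: KineticsModel | Sequence[KineticsModel],
    seed: int | None = None,
) -> PopulationSim:
    """Simulate a full session for a population of cells.

    Spike trains are drawn per cell, turned into cytosolic traces on a
    contiguous session frame grid (transients carry across trial
    boundaries), and contaminated with a shared neuropil trace whose
    fluctuations follow population-average activity — so neuropil
    contamination is correlated with signal, as the correction model
    assumes.
    """
    n_cells = len(tuning)
    kin = list(kinetics) if isinstance(kinetics, (list, tuple)) else [kinetics] * n_cells
    if len(kin) != n_cells:
        raise ConfigurationError("kinetics list must match tuning list length")
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    spike_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))

    t_frames = protocol.session_frames
    cyto = np.empty((n_cells, t_frames))
    spikes: list[list[np.ndarray]] = []
    for i in range(n_cells):
        trains = generate_spike_trains(tuning[i], protocol, spike_rng)
        spikes.append(trains)
        cyto[i] = spikes_to_fluorescence(trains, kin[i], protocol, n_frames=t_frames)

    bases = np.array([k.baseline_fluorescence for k in kin])
    if n_cells:
        pop_dff = np.mean((cyto - bases[:, None]) / bases[:, None], axis=0)
    else:
        pop_dff = np.zeros(t_frames)
    np_base = scene.neuropil_amplitude * (bases.mean() if n_cells else 1.0)
    neuropil = np_base * (1.0 + scene.neuropil_coupling * pop_dff)

    measured, measured_np = compose_measurement(cyto, neuropil, scene, rng=noise_rng)
    truth = GroundTruth(
        spike_times=spikes,
        tuning=list(tuning),
        kinetics=kin,
        cytosolic_traces=cyto,
        neuropil_trace=neuropil,
        contamination_ratio_true=scene.contamination_ratio_true,
    )
    return PopulationSim(
        protocol=protocol,
        scene=scene,
        truth=truth,
        measured=measured,
        measured_neuropil=measured_np,
        trial_table=protocol.trial_table(),
    )


# ----------------------------------------------------------------------
# movie rendering
def _place_centers(
    n: int,
    bounds: tuple[float, float],
    margin: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` centers (same units as bounds) with a minimum
    pairwise separation; raises :class:`PlacementError` when the density is
    too high for the bounded retry budget."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{n} somata after {max_tries} tries"
            )
        tries += 1
        y = rng.uniform(margin, bounds[0] - margin)
        x = rng.uniform(margin, bounds[1] - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))
    return np.array(centers).reshape(n, 2)


def _smooth_field(shape: tuple[int, int], sigma_px: float, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Static multiplicative neuropil texture, mean ~1, SD ~``amplitude``."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma_px)
    sd = noise.std()
    if sd == 0:
        return np.ones(shape)
    field = 1.0 + amplitude * noise / sd
    return np.clip(field, 0.1, None)


def render_movie(
    sim: PopulationSim,
    centers_um: np.ndarray | None = None,
    texture_amplitude: float = 0.1,
    nucleus_dimming: float = 0.3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the simulated session as a movie (frames, rows, cols).

    Somata are drawn as nucleus-excluded rings carrying the cell's
    cytosolic signal plus see-through neuropil; the background is the
    neuropil trace times a static smooth spatial texture.  Returns the
    float32 stack and the cell centers in µm (row, col).  Per-pixel
    Gaussian noise follows ``scene.gaussian_noise_fraction``.
    """
    scene = sim.scene
    rng = np.random.default_rng(scene.seed + 1) if rng is None else rng
    ps = scene.pixel_size
    h, w = scene.image_size
    n_cells = sim.n_cells
    if centers_um is None:
        centers_um = _place_centers(
            n_cells,
            (h * ps, w * ps),
            margin=scene.soma_radius + 2.0,
            min_sep=2.0 * scene.soma_radius + 2.0,
            rng=rng,
        )
    centers_um = np.asarray(centers_um, dtype=float).reshape(n_cells, 2)

    yy, xx = np.meshgrid(
        (np.arange(h) + 0.5) * ps, (np.arange(w) + 0.5) * ps, indexing="ij"
    )
    ring_masks, nuc_masks = [], []
    for cy, cx in centers_um:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring_masks.append((d2 < scene.soma_radius**2) & (d2 >= scene.nucleus_radius**2))
        nuc_masks.append(d2 < scene.nucleus_radius**2)

    texture = _smooth_field((h, w), sigma_px=20.0, amplitude=texture_amplitude, rng=rng)
    t_frames = sim.measured.shape[1]
    stack = np.empty((t_frames, h, w), dtype=np.float32)
    r = scene.contamination_ratio_true
    cyto = sim.truth.cytosolic_traces
    npil = sim.truth.neuropil_trace
    noise_sd = 0.0
    if scene.gaussian_noise_fraction > 0:
        noise_sd = scene.gaussian_noise_fraction * float(
            np.mean([k.baseline_fluorescence for k in sim.truth.kinetics])
        )
    for t in range(t_frames):
        frame = texture * npil[t]
        for i in range(n_cells):
            frame = np.where(ring_masks[i], cyto[i, t] + r * texture * npil[t], frame)
            frame = np.where(
                nuc_masks[i], nucleus_dimming * cyto[i, t] + r * texture * npil[t], frame
            )
        if noise_sd > 0:
            frame = frame + rng.standard_normal((h, w)) * noise_sd
        stack[t] = frame
    return stack, centers_um


# ----------------------------------------------------------------------
# histology generator
@dataclass
class HistologyScene:
    """Two-channel histology image pair plus bead field and truth table."""

    green: np.ndarray  # GCaMP-like channel
    red: np.ndarray  # NeuN-like channel (all neurons)
    beads: np.ndarray  # fluorescent-bead field
    truth: pd.DataFrame  # row, col (px), labeled, green_brightness, red_brightness
    pixel_size: float  # µm/pixel
    soma_radius: float  # µm
    nucleus_radius: float  # µm


def generate_histology_image(
    n_cells: int = 120,
    labeled_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    image_size: tuple[int, int] = (512, 512),
    pixel_size: float = 0.5,
    soma_radius: float = 6.0,
    nucleus_radius: float = 3.0,
    mean_brightness: float = 1000.0,
    brightness_sigma: float = 0.5,
    background: float = 30.0,
    noise_sd: float = 8.0,
    n_beads: int = 12,
    bead_diameter: float = 3.8,
    bead_brightness: float = 2000.0,
    illumination: float = 1.0,
) -> HistologyScene:
    """Render a confocal-like two-channel histology scene with beads.

    The red channel shows every soma as a filled disk (NeuN-like
    counterstain); the green channel shows a ``labeled_fraction`` subset
    as nucleus-excluded rings whose brightness is drawn from a lognormal
    with median ``mean_brightness`` and log-SD ``brightness_sigma``.  A
    separate bead field contains disks of ``bead_diameter`` µm.  All
    signal (cells, background, beads) scales with ``illumination``,
    emulating session-to-session excitation changes that bead
    normalization is meant to remove.
    """
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ConfigurationError("labeled_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = image_size
    r_px = soma_radius / pixel_size
    centers = _place_centers(
        n_cells, (float(h), float(w)), margin=r_px + 2, min_sep=2 * r_px + 3, rng=rng
    )
    labeled = rng.uniform(size=n_cells) < labeled_fraction
    green_b = np.exp(rng.normal(np.log(mean_brightness), brightness_sigma, n_cells))
    red_b = np.exp(rng.normal(np.log(0.8 * mean_brightness), 0.3, n_cells))

    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    green = np.full((h, w), float(background))
    red = np.full((h, w), float(background))
    nuc_px = nucleus_radius / pixel_size
    for i, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = d2 < r_px**2
        red[disk] = red_b[i]
        if labeled[i]:
            ring = disk & (d2 >= nuc_px**2)
            green[ring] = green_b[i]

    beads = np.full((h, w), float(background))
    bead_r_px = bead_diameter / 2.0 / pixel_size
    bead_centers = _place_centers(
        n_beads, (float(h), float(w)), margin=bead_r_px + 2,
        min_sep=4 * bead_r_px, rng=rng,
    )
    for cy, cx in bead_centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        beads[d2 < bead_r_px**2] = bead_brightness * (1.0 + 0.05 * rng.standard_normal())

    green = illumination * green + rng.standard_normal((h, w)) * noise_sd
    red = illumination * red + rng.standard_normal((h, w)) * noise_sd
    beads = illumination * beads + rng.standard_normal((h, w)) * noise_sd

    truth = pd.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "labeled": labeled,
            "green_brightness": illumination * green_b,
            "red_brightness": illumination * red_b,
        }
    )
    return HistologyScene(
        green=green, red=red, beads=beads, truth=truth,
        pixel_size=pixel_size, soma_radius=soma_radius, nucleus_radius=nucleus_radius,
    )
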