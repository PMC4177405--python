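"""Generative model components: indicator kinetics, direction tuning, scene.

These dataclasses parameterize the forward simulator.  Two indicator
presets are provided: a fast GCaMP6f-like indicator and a slow
GCaMP6s-like indicator, differing mainly in transient decay half-time.
The preset half-decay values (0.14 s fast, 0.51 s slow) are simulator
parameters chosen to lie in the range measured for these indicators in
cortical tissue; they are inputs to the simulation, not claims about any
particular preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError

__all__ = [
    "KineticsModel",
    "TuningModel",
    "SceneModel",
    "FAST_INDICATOR",
    "SLOW_INDICATOR",
    "indicator_preset",
]


@dataclass(frozen=True)
class KineticsModel:
    """Single-spike fluorescence transient parameters.

    The transient is a difference of exponentials; ``decay_half_time`` is
    the time for the post-peak transient to fall to half its peak (the
    decay time constant is calibrated so this holds exactly).

    Parameters
    ----------
    rise_time
        Rise time constant in seconds.
    decay_half_time
        Post-peak half-decay time in seconds; must exceed ``rise_time``.
    amplitude_per_spike
        Peak dF/F contributed by one spike (transients sum linearly).
    baseline_fluorescence
        Resting fluorescence in arbitrary units.
    label
        Indicator name, e.g. ``"fast"`` or ``"slow"``.
    """

    rise_time: float
    decay_half_time: float
    amplitude_per_spike: float
    baseline_fluorescence: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.rise_time < self.decay_half_time:
            raise ConfigurationError("rise_time must be < decay_half_time")
        if self.rise_time <= 0:
            raise ConfigurationError("rise_time must be > 0")
        if self.amplitude_per_spike <= 0:
            raise ConfigurationError("amplitude_per_spike must be > 0")
        if self.baseline_fluorescence <= 0:
            raise ConfigurationError("baseline_fluorescence must be > 0")


FAST_INDICATOR = KineticsModel(
    rise_time=0.045,
    decay_half_time=0.14,
    amplitude_per_spike=0.19,
    baseline_fluorescence=100.0,
    label="fast",
)

SLOW_INDICATOR = KineticsModel(
    rise_time=0.18,
    decay_half_time=0.51,
    amplitude_per_spike=0.25,
    baseline_fluorescence=100.0,
    label="slow",
)


def indicator_preset(name: str) -> KineticsModel:
    """Return the ``"fast"`` or ``"slow"`` indicator preset."""
    try:
        return {"fast": FAST_INDICATOR, "slow": SLOW_INDICATOR}[name]
    except KeyError:
        raise ConfigurationError(f"unknown indicator preset {name!r}") from None


@dataclass(frozen=True)
class TuningModel:
    """Direction tuning and rate modulation of one simulated neuron.

    Firing rate during the grating is

    ``baseline + (peak - baseline) * g(dir - preferred) *
    (1 + modulation_depth * sin(2 pi f_t t))``

    where ``g`` is a von Mises-shaped gain normalized to 1 at the
    preferred direction and ``f_t`` the grating temporal frequency.
    Untuned cells (``is_tuned=False``) fire at ``baseline_rate``
    throughout.
    """

    preferred_direction: float = 0.0
    tuning_width: float = 2.0  # von Mises concentration (dimensionless)
    baseline_rate: float = 2.0  # spikes/s
    peak_rate: float = 10.0  # spikes/s
    modulation_depth: float = 0.5  # fraction in [0, 1]
    is_tuned: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.preferred_direction < 360.0:
            raise ConfigurationError("preferred_direction must be in [0, 360)")
        if self.baseline_rate < 0 or self.peak_rate < self.baseline_rate:
            raise ConfigurationError("need peak_rate >= baseline_rate >= 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ConfigurationError("modulation_depth must be in [0, 1]")
        if self.tuning_width < 0:
            raise ConfigurationError("tuning_width must be >= 0")

    def untuned(self) -> "TuningModel":
        """Copy of this model with no stimulus-driven response."""
        return replace(self, peak_rate=self.baseline_rate, is_tuned=False,
                       modulation_depth=0.0)


@dataclass(frozen=True)
class SceneModel:
    """Imaging-scene geometry, contamination, and noise.

    The measured somatic signal is
    ``cytosolic + contamination_ratio_true * neuropil + noise``; the
    neuropil trace has baseline ``neuropil_amplitude *
    baseline_fluorescence`` and co-fluctuates with population-average
    activity (coupling ``neuropil_coupling``).

    Noise is additive Gaussian with SD ``gaussian_noise_fraction`` times
    the cell's baseline fluorescence, or Poisson photon noise when
    ``photon_scaling`` (photons per intensity unit) is set.
    """

    field_of_view: tuple[float, float] = (250.0, 250.0)  # µm
    image_size: tuple[int, int] = (512, 512)  # pixels (rows, cols)
    n_cells: int = 50
    soma_radius: float = 6.0  # µm
    nucleus_radius: float = 3.0  # µm
    neuropil_amplitude: float = 0.7  # fraction of soma baseline brightness
    neuropil_coupling: float = 1.0  # gain from population dF/F to neuropil
    contamination_ratio_true: float = 0.7
    gaussian_noise_fraction: float = 0.05
    photon_scaling: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nucleus_radius < self.soma_radius:
            raise ConfigurationError("nucleus_radius must be < soma_radius")
        if not 0.0 <= self.contamination_ratio_true <= 1.0:
            raise ConfigurationError("contamination_ratio_true must be in [0, 1]")
        if self.gaussian_noise_fraction < 0:
            raise ConfigurationError("gaussian_noise_fraction must be >= 0")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")

    @property
    def pixel_size(self) -> float:
        """µm per pixel (isotropic; rows and cols must agree)."""
        py = self.field_of_view[0] / self.image_size[0]
        px = self.field_of_view[1] / self.image_size[1]
        if abs(py - px) > 1e-9:
            raise ConfigurationError("anisotropic pixels are not supported")
        return py
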