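"""Acquisition and population configuration.

All optical path lengths are in nanometres, times in seconds, rates in s^-1.
The time axis places the stimulus flash at t = 0: the two baseline volumes
sit at negative times and the first post-stimulus volume at t = 1/volume_rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "PopulationConfig",
    "lateral_sampling_intervals",
    "nyquist_interval",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and optics of one optoretinography recording.

    Parameters
    ----------
    volume_rate : float
        OCT volume rate in Hz.
    n_volumes : int
        Number of post-stimulus volumes.
    n_baseline_volumes : int
        Pre-stimulus volumes used for phase referencing (at least 2).
    stimulus_duration : float
        Flash duration in seconds (metadata only; the response model treats
        the flash as impulsive at t = 0).
    wavelength : float
        Imaging centre wavelength in nm, used in the phase-to-OPL scaling
        dOPL = dphi * lambda / (4 pi).
    region_size : int
        Side of the square pixel region segmenting one cone.
    m_brightest : int
        Number of brightest A-scans averaged by the phase estimator.
    max_unwrap_gap : int
        Longest run of consecutive masked timepoints across which temporal
        unwrapping is still trusted; longer gaps disqualify the cone.
    time_offset : float
        Sub-frame offset (s) of the first post-stimulus sample relative to
        1/volume_rate. Default 0.
    """

    volume_rate: float = 28.0
    n_volumes: int = 42
    n_baseline_volumes: int = 2
    stimulus_duration: float = 0.010
    wavelength: float = 1063.0
    region_size: int = 7
    m_brightest: int = 9
    max_unwrap_gap: int = 3
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")
        if self.n_volumes < 1:
            raise ValueError("need at least one post-stimulus volume")
        if self.n_baseline_volumes < 2:
            raise ValueError("phase referencing needs >= 2 baseline volumes")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.region_size < 1:
            raise ValueError("region_size must be >= 1")
        if not 1 <= self.m_brightest <= self.region_size**2:
            raise ValueError("m_brightest must lie in [1, region_size**2]")

    @property
    def n_timepoints(self) -> int:
        return self.n_baseline_volumes + self.n_volumes

    def times(self) -> np.ndarray:
        """Full time vector (s), baseline volumes at negative times."""
        dt = 1.0 / self.volume_rate
        k = np.concatenate([np.arange(-self.n_baseline_volumes, 0),
                            np.arange(1, self.n_volumes + 1)])
        return k * dt + self.time_offset

    def post_stimulus_times(self) -> np.ndarray:
        return self.times()[self.n_baseline_volumes:]

    def phase_per_nm(self) -> float:
        """Radians of ISOS-COST phase per nm of outer-segment OPL change."""
        return 4.0 * math.pi / self.wavelength

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


@dataclass(frozen=True)
class PopulationConfig:
    """Statistical structure of the simulated cone population.

    The per-cone response parameters (A1, tau_a, tau_b) are drawn from
    normal distributions truncated at zero, with the ordering tau_a > tau_b
    enforced by resampling. A fixed fraction of cones emulates the weakly
    responding S-cone subpopulation with uniformly small amplitudes.

    snr_db is the amplitude signal-to-noise ratio of the OCT samples in dB;
    per-layer circular phase noise has SD 1/SNR (linear). ``None`` or
    ``inf`` means noiseless.
    """

    n_cones: int = 300
    mean_A1: float = 200.0
    sd_A1: float = 46.0
    mean_tau_a: float = 8.0
    sd_tau_a: float = 2.0
    mean_tau_b: float = 1.0
    sd_tau_b: float = 0.3
    s_cone_fraction: float = 0.05
    s_cone_amplitude_range: tuple[float, float] = (30.0, 50.0)
    trial_noise_sd: float = 10.0
    snr_db: float | None = 20.0
    dropout_rate: float = 0.05
    baseline_drift_rms: float = 2.5

    def __post_init__(self) -> None:
        if self.n_cones < 1:
            raise ValueError("n_cones must be positive")
        for name in ("sd_A1", "sd_tau_a", "sd_tau_b", "trial_noise_sd",
                     "baseline_drift_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.s_cone_fraction < 1:
            raise ValueError("s_cone_fraction must lie in [0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        lo, hi = self.s_cone_amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("s_cone_amplitude_range must be 0 < lo <= hi")

    @property
    def phase_noise_sd(self) -> float:
        """Per-layer, per-A-scan circular phase noise SD in radians."""
        if self.snr_db is None or math.isinf(self.snr_db):
            return 0.0
        return 10.0 ** (-self.snr_db / 20.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["s_cone_amplitude_range"] = list(self.s_cone_amplitude_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        if "s_cone_amplitude_range" in d:
            d["s_cone_amplitude_range"] = tuple(d["s_cone_amplitude_range"])
        return cls(**d)


def config_hash(*configs) -> str:
    """Short stable hash of one or more config objects, for output headers."""
    blob = json.dumps([c.to_dict() for c in configs], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def lateral_sampling_intervals(
    n_fast: int = 160, n_slow: int = 172, fov_um: float = 300.0
) -> tuple[float, float]:
    """Lateral sampling intervals (um) of the raster scan.

    A 1 degree field of view (~300 um on the retina) sampled by
    ``n_fast`` A-scans per B-scan and ``n_slow`` B-scans.
    """
    return fov_um / n_fast, fov_um / n_slow

def nyquist_interval(resolution_um: float = 3.2) -> float:
    """Minimum sampling interval (um) to critically sample a given
    lateral resolution for a continuous signal."""
    return resolution_um / 2.0
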