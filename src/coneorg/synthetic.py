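"""Synthetic complex AO-OCT cone signals with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a population of cones whose outer segments elongate after a flash
following the overdamped difference-of-exponentials model, with
  * between-cone heterogeneity of (A1, tau_a, tau_b),
  * an S-cone-like subpopulation with uniformly small amplitudes,
  * cone-level trial-to-trial jitter of the response parameters,
  * a slow baseline optical-path drift,
  * a random piston phase per volume common to both layers (bulk axial
    motion), cancelled by the conjugate-product estimator,
  * per-A-scan circular phase noise set by the OCT amplitude SNR, and
  * randomly masked timepoints emulating eye-motion dropout.

The clean dOPL(t) is encoded into the COST layer phase relative to ISOS via
dphi = 4 pi dOPL / lambda, the inverse of the extraction scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .config import AcquisitionConfig, PopulationConfig
from .model import rlc_model

__all__ = [
    "GroundTruth",
    "ConeRecord",
    "make_cone_population",
    "clean_dopl",
    "simulate_trial",
    "simulate_dataset",
    "simulate_traces",
    "write_dataset",
    "read_dataset",
]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class GroundTruth:
    """True per-cone response parameters of a simulated population."""

    a1: np.ndarray        # nm
    tau_a: np.ndarray     # s^-1
    tau_b: np.ndarray     # s^-1
    is_s_cone: np.ndarray # bool, weak-response subpopulation

    @property
    def n_cones(self) -> int:
        return self.a1.size


@dataclass
class ConeRecord:
    """Complex OCT samples at both outer-segment boundaries for one cone
    in one trial. Masked timepoints are flagged, never zeroed."""

    cone_id: int
    trial_id: int
    isos: np.ndarray        # (region_size**2, n_timepoints) complex
    cost: np.ndarray        # same shape
    amplitudes: np.ndarray  # (region_size**2,) mean reflectance per A-scan
    mask: np.ndarray        # (n_timepoints,) bool, True = lost to motion
    position: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.isos.shape != self.cost.shape:
            raise ValueError("ISOS and COST arrays must share shape")


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    """Normal draw resampled until strictly above ``lower``."""
    x = rng.normal(mean, sd, size)
    for _ in range(_MAX_RESAMPLE):
        bad = x <= lower
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValueError("could not draw positive parameters; check mean/sd")


def make_cone_population(pop: PopulationConfig, seed) -> GroundTruth:
    """Draw per-cone true parameters.

    (A1, tau_a, tau_b) come from normals truncated at zero; pairs violating
    tau_a > tau_b are resampled (bounded attempts). A fraction of cones is
    relabelled S-cone-like and reassigned amplitudes uniform in
    ``s_cone_amplitude_range``.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_cones
    a1 = _truncated_normal(rng, pop.mean_A1, pop.sd_A1, n)
    tau_a = _truncated_normal(rng, pop.mean_tau_a, pop.sd_tau_a, n)
    tau_b = _truncated_normal(rng, pop.mean_tau_b, pop.sd_tau_b, n)
    for _ in range(_MAX_RESAMPLE):
        bad = tau_a <= tau_b
        if not bad.any():
            break
        k = int(bad.sum())
        tau_a[bad] = _truncated_normal(rng, pop.mean_tau_a, pop.sd_tau_a, k)
        tau_b[bad] = _truncated_normal(rng, pop.mean_tau_b, pop.sd_tau_b, k)
    else:
        raise ValueError("could not enforce tau_a > tau_b; check rate configs")

    is_s = rng.random(n) < pop.s_cone_fraction
    lo, hi = pop.s_cone_amplitude_range
    a1[is_s] = rng.uniform(lo, hi, int(is_s.sum()))
    return GroundTruth(a1=a1, tau_a=tau_a, tau_b=tau_b, is_s_cone=is_s)


def clean_dopl(times, a1, tau_a, tau_b):
    """Noise-free dOPL(t) in nm: zero before stimulus onset, model after."""
    t = np.asarray(times, dtype=float)
    return np.where(t < 0, 0.0, rlc_model(np.maximum(t, 0.0), a1, tau_a, tau_b))


def _realize_trial_params(gt: GroundTruth, pop: PopulationConfig, rng):
    """Cone-level trial-to-trial jitter.

    The configured jitter SD (nm) is converted to a relative scale against
    the population mean amplitude; amplitudes are jittered multiplicatively
    and rates on the log scale (at twice the relative SD, reflecting the
    larger trial-to-trial variation of kinetics than of amplitudes).
    """
    n = gt.n_cones
    rel = pop.trial_noise_sd / pop.mean_A1
    a1 = gt.a1 * np.maximum(1.0 + rng.normal(0.0, rel, n), 1e-3)
    tau_a = gt.tau_a * np.exp(rng.normal(0.0, 2.0 * rel, n))
    tau_b = gt.tau_b * np.exp(rng.normal(0.0, 2.0 * rel, n))
    # keep the ordering; jitter is small so a hard floor suffices
    tau_b = np.minimum(tau_b, 0.9 * tau_a)
    return a1, tau_a, tau_b


def _baseline_drift(rng, n_t: int, rms: float) -> np.ndarray:
    """Slow optical-path drift: a Gaussian random walk rescaled to the
    requested RMS over the recording."""
    if rms <= 0:
        return np.zeros(n_t)
    walk = np.cumsum(rng.normal(0.0, 1.0, n_t))
    walk -= walk.mean()
    scale = np.sqrt(np.mean(walk**2))
    return walk * (rms / scale) if scale > 0 else walk


def simulate_trial(gt: GroundTruth, acq: AcquisitionConfig,
                   pop: PopulationConfig, seed, *,
                   trial_id: int = 0,
                   stimulus_on: bool = True) -> list[ConeRecord]:
    """Generate the complex two-layer records of one trial.

    With ``stimulus_on=False`` the clean response is zero everywhere (the
    no-stimulus control); noise, drift, piston and dropout still apply.
    """
    rng = np.random.default_rng(seed)
    sigma = pop.phase_noise_sd
    if sigma > math.pi:
        raise ValueError("phase noise SD exceeds pi; estimator assumptions void")

    times = acq.times()
    n_t = times.size
    n_pix = acq.region_size**2
    k_phase = acq.phase_per_nm()

    a1, tau_a, tau_b = _realize_trial_params(gt, pop, rng)
    # dOPL steps > lambda/4 (phase steps > pi) would break unwrapping
    max_step = acq.wavelength / 4.0
    records = []
    for j in range(gt.n_cones):
        if stimulus_on:
            dopl = clean_dopl(times, a1[j], tau_a[j], tau_b[j])
        else:
            dopl = np.zeros(n_t)
        dopl = dopl + _baseline_drift(rng, n_t, pop.baseline_drift_rms)
        steps = np.abs(np.diff(dopl))
        if steps.size and steps.max() >= max_step:
            raise ValueError(
                "dOPL increment exceeds lambda/4 between samples; "
                "unwrapping would fail for this configuration")

        piston = rng.uniform(-math.pi, math.pi, n_t)
        amps = rng.lognormal(mean=0.0, sigma=0.5, size=n_pix)
        noise_i = rng.normal(0.0, sigma, (n_pix, n_t)) if sigma else 0.0
        noise_c = rng.normal(0.0, sigma, (n_pix, n_t)) if sigma else 0.0
        phase_c = piston[None, :] + k_phase * dopl[None, :] + noise_c
        phase_i = piston[None, :] + noise_i
        isos = amps[:, None] * np.exp(1j * phase_i)
        cost = amps[:, None] * np.exp(1j * phase_c)

        mask = rng.random(n_t) < pop.dropout_rate
        records.append(ConeRecord(
            cone_id=j, trial_id=trial_id, isos=isos, cost=cost,
            amplitudes=amps, mask=mask,
            position=(j % 100, j // 100),
        ))
    return records


def simulate_dataset(pop: PopulationConfig, acq: AcquisitionConfig,
                     n_trials: int, seed, *, stimulus_on: bool = True,
                     path=None):
    """Simulate ``n_trials`` repeated recordings of one cone population.

    All trials share one GroundTruth; noise realizations are independent
    (child seeds spawned deterministically from ``seed``). If ``path`` is
    given the dataset is also written to an HDF5 container.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    gt = make_cone_population(pop, children[0])
    trials = [
        simulate_trial(gt, acq, pop, children[1 + k], trial_id=k,
                       stimulus_on=stimulus_on)
        for k in range(n_trials)
    ]
    if path is not None:
        write_dataset(path, trials, gt, acq)
    return trials, gt


def simulate_traces(n_cones: int, seed, *,
                    mean_A1: float = 200.0, sd_A1: float = 46.0,
                    mean_tau_a: float = 8.0, sd_tau_a: float = 2.0,
                    mean_tau_b: float = 1.0, sd_tau_b: float = 0.3,
                    noise_rms: float = 15.0,
                    volume_rate: float = 28.0, duration: float = 1.4):
    """Trace-level cohort: noisy dOPL(t) directly from the response model.

    Bypasses the complex-signal encoding; used for model-recovery studies
    where the quantity of interest is the fitter, not the phase estimator.
    Post-stimulus samples at t = k/volume_rate, k = 1..floor(duration*rate),
    with i.i.d. Gaussian noise of the given RMS (nm).

    Returns ``(t, traces, truth)`` with traces shaped (n_cones, n_t) and
    truth a dict of arrays a1, tau_a, tau_b.
    """
    rng = np.random.default_rng(seed)
    a1 = _truncated_normal(rng, mean_A1, sd_A1, n_cones)
    tau_a = _truncated_normal(rng, mean_tau_a, sd_tau_a, n_cones)
    tau_b = _truncated_normal(rng, mean_tau_b, sd_tau_b, n_cones)
    for _ in range(_MAX_RESAMPLE):
        bad = tau_a <= tau_b
        if not bad.any():
            break
        tau_a[bad] = _truncated_normal(rng, mean_tau_a, sd_tau_a, int(bad.sum()))
        tau_b[bad] = _truncated_normal(rng, mean_tau_b, sd_tau_b, int(bad.sum()))
    n_t = int(math.floor(duration * volume_rate))
    t = np.arange(1, n_t + 1) / volume_rate
    clean = a1[:, None] * (np.exp(-tau_b[:, None] * t)
                           - np.exp(-tau_a[:, None] * t))
    traces = clean + rng.normal(0.0, noise_rms, clean.shape)
    return t, traces, {"a1": a1, "tau_a": tau_a, "tau_b": tau_b}


def write_dataset(path, trials, gt: GroundTruth, acq: AcquisitionConfig):
    """Write trials and ground truth to an HDF5 container.

    Layout: /trial_<k>/cone_<j> with datasets isos, cost, amplitudes, mask;
    acquisition parameters as file attributes; /ground_truth with per-cone
    parameter tables.
    """
    with h5py.File(path, "w") as f:
        for key, val in acq.to_dict().items():
            f.attrs[key] = val
        f.attrs["n_trials"] = len(trials)
        g = f.create_group("ground_truth")
        g.create_dataset("a1", data=gt.a1)
        g.create_dataset("tau_a", data=gt.tau_a)
        g.create_dataset("tau_b", data=gt.tau_b)
        g.create_dataset("is_s_cone", data=gt.is_s_cone)
        for k, records in enumerate(trials):
            tg = f.create_group(f"trial_{k}")
            for rec in records:
                cg = tg.create_group(f"cone_{rec.cone_id}")
                cg.create_dataset("isos", data=rec.isos)
                cg.create_dataset("cost", data=rec.cost)
                cg.create_dataset("amplitudes", data=rec.amplitudes)
                cg.create_dataset("mask", data=rec.mask)
                cg.attrs["position"] = rec.position


def read_dataset(path):
    """Read an HDF5 container back into (trials, GroundTruth, AcquisitionConfig)."""
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        n_trials = int(attrs.pop("n_trials"))
        attrs = {k: (int(v) if isinstance(v, np.integer) else
                     float(v) if isinstance(v, np.floating) else v)
                 for k, v in attrs.items()}
        acq = AcquisitionConfig.from_dict(attrs)
        g = f["ground_truth"]
        gt = GroundTruth(a1=g["a1"][:], tau_a=g["tau_a"][:],
                         tau_b=g["tau_b"][:], is_s_cone=g["is_s_cone"][:])
        trials = []
        for k in range(n_trials):
            tg = f[f"trial_{k}"]
            records = []
            for j in range(gt.n_cones):
                cg = tg[f"cone_{j}"]
                records.append(ConeRecord(
                    cone_id=j, trial_id=k,
                    isos=cg["isos"][:], cost=cg["cost"][:],
                    amplitudes=cg["amplitudes"][:], mask=cg["mask"][:],
                    position=tuple(cg.attrs["position"]),
                ))
            trials.append(records)
    return trials, gt, acq
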