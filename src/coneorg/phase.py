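"""Phase-difference extraction: complex two-layer cone signals -> dOPL(t).

The outer-segment length change of a cone is encoded in the phase difference
between the reflections at the inner-outer segment junction (ISOS) and the
cone outer segment tip (COST). Per timepoint the estimator averages the
conjugate products of the m brightest A-scans inside the cone's pixel region,

    dphi_t = angle( (1/m) * sum_i  COST_i * conj(ISOS_i) ),

which cancels any piston phase common to both layers (axial bulk motion).
After referencing to the pre-stimulus baseline and temporal unwrapping, the
phase is scaled to optical path length by dOPL = dphi * lambda / (4 pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig
from .errors import ConeExcludedError

__all__ = [
    "PhaseSeries",
    "OplTrace",
    "select_brightest",
    "phase_difference",
    "to_opl_trace",
    "extract_dataset",
]


@dataclass(frozen=True)
class PhaseSeries:
    """Wrapped ISOS-COST phase difference per timepoint, radians in (-pi, pi]."""

    cone_id: int
    trial_id: int
    phase: np.ndarray           # (n_timepoints,), NaN where masked
    mask: np.ndarray            # (n_timepoints,) bool, True = unusable
    indices: np.ndarray         # selected A-scan indices (per-trial selection)


@dataclass(frozen=True)
class OplTrace:
    """Baseline-referenced outer-segment OPL change in nm."""

    cone_id: int
    trial_id: int
    time: np.ndarray            # (n_timepoints,) s, stimulus onset at 0
    dopl: np.ndarray            # (n_timepoints,) nm, NaN where masked
    mask: np.ndarray            # bool, True = unusable
    n_baseline_used: int


def select_brightest(amplitude_map, m: int) -> np.ndarray:
    """Indices of the ``m`` largest amplitudes, ties broken by lowest index."""
    amps = np.asarray(amplitude_map, dtype=float).ravel()
    if not 1 <= m <= amps.size:
        raise ValueError(f"m={m} outside [1, {amps.size}]")
    order = np.argsort(-amps, kind="stable")  # stable: ties keep low index first
    return np.sort(order[:m])


def _wrap(phi):
    """Map angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def phase_difference(record, indices=None, *, m: int | None = None,
                     select_per_timepoint: bool = False) -> PhaseSeries:
    """Conjugate-product phase estimator for one cone record.

    ``indices`` overrides A-scan selection; otherwise the ``m`` brightest
    are chosen from the record's amplitude map (default), or per timepoint
    from the product magnitudes when ``select_per_timepoint`` is set.
    Timepoints where the averaged phasor vanishes are masked.
    """
    isos = np.asarray(record.isos)
    cost = np.asarray(record.cost)
    if isos.shape != cost.shape:
        raise ValueError("ISOS and COST arrays must share shape")
    n_t = isos.shape[1]
    mask = np.asarray(record.mask, dtype=bool).copy()
    products = cost * np.conj(isos)  # (n_pix, n_t)

    if select_per_timepoint:
        if m is None:
            raise ValueError("per-timepoint selection requires m")
        mag = np.abs(products)
        phasor = np.empty(n_t, dtype=complex)
        for t in range(n_t):
            idx = select_brightest(mag[:, t], m)
            phasor[t] = products[idx, t].mean()
        sel = np.arange(isos.shape[0])  # selection varies per timepoint
    else:
        if indices is None:
            if m is None:
                raise ValueError("provide indices or m")
            indices = select_brightest(record.amplitudes, m)
        sel = np.asarray(indices)
        phasor = products[sel, :].mean(axis=0)

    dead = np.abs(phasor) == 0.0
    mask |= dead
    phase = np.where(mask, np.nan, np.angle(phasor))
    return PhaseSeries(cone_id=record.cone_id, trial_id=record.trial_id,
                       phase=phase, mask=mask, indices=sel)


def _unwrap_masked(delta: np.ndarray, mask: np.ndarray,
                   max_gap: int) -> np.ndarray:
    """Temporally unwrap a wrapped series, skipping masked points.

    Adds multiples of 2 pi so successive unmasked differences lie in
    (-pi, pi]. A run of more than ``max_gap`` masked points makes the 2 pi
    ambiguity across the gap untrustworthy and raises ConeExcludedError.
    """
    idx = np.flatnonzero(~mask)
    if idx.size == 0:
        raise ConeExcludedError("all timepoints masked")
    gaps = np.diff(idx) - 1
    if gaps.size and gaps.max() > max_gap:
        raise ConeExcludedError(
            f"masked gap of {int(gaps.max())} samples exceeds {max_gap}"
        )
    vals = delta[idx]
    # np.unwrap uses period 2*pi and the same +-pi jump criterion
    unwrapped = np.unwrap(vals)
    out = np.full(delta.shape, np.nan)
    out[idx] = unwrapped
    return out


def to_opl_trace(series: PhaseSeries, acq: AcquisitionConfig) -> OplTrace:
    """Baseline-reference, unwrap and scale a phase series to nm.

    The reference phase is the circular mean of the unmasked baseline
    (pre-stimulus) phases — computed on the complex unit circle so baselines
    straddling +-pi do not wrap. At least one unmasked baseline volume is
    required; cones failing this, or with motion gaps longer than
    ``acq.max_unwrap_gap``, raise ConeExcludedError.
    """
    nb = acq.n_baseline_volumes
    phase = np.asarray(series.phase, dtype=float)
    mask = np.asarray(series.mask, dtype=bool)
    if phase.size != acq.n_timepoints:
        raise ValueError("phase series length does not match acquisition")

    base_ok = ~mask[:nb]
    n_used = int(base_ok.sum())
    if n_used == 0:
        raise ConeExcludedError("all baseline volumes masked")
    ref = np.angle(np.mean(np.exp(1j * phase[:nb][base_ok])))

    delta = _wrap(np.where(mask, 0.0, phase) - ref)
    unwrapped = _unwrap_masked(delta, mask, acq.max_unwrap_gap)
    dopl = unwrapped * (acq.wavelength / (4.0 * np.pi))
    dopl[mask] = np.nan
    return OplTrace(cone_id=series.cone_id, trial_id=series.trial_id,
                    time=acq.times(), dopl=dopl, mask=mask,
                    n_baseline_used=n_used)


def extract_dataset(trials, acq: AcquisitionConfig, *,
                    m: int | None = None,
                    select_per_timepoint: bool = False):
    """Run phase extraction over a full dataset.

    Parameters
    ----------
    trials : sequence of sequences of ConeRecord
        As returned by the simulator (one inner list per trial).
    acq : AcquisitionConfig
    m : int, optional
        Number of brightest A-scans (default ``acq.m_brightest``).

    Returns
    -------
    (pandas.DataFrame, list[tuple])
        Tidy trace table (cone_id, trial_id, t_s, dopl_nm, masked) and a
        list of (cone_id, trial_id, reason) exclusions.
    """
    import pandas as pd

    if m is None:
        m = acq.m_brightest
    times = acq.times()
    frames, exclusions = [], []
    for records in trials:
        for rec in records:
            try:
                series = phase_difference(
                    rec, m=m, select_per_timepoint=select_per_timepoint)
                trace = to_opl_trace(series, acq)
            except ConeExcludedError as exc:
                exclusions.append((rec.cone_id, rec.trial_id, str(exc)))
                continue
            frames.append(pd.DataFrame({
                "cone_id": rec.cone_id, "trial_id": rec.trial_id,
                "t_s": times, "dopl_nm": trace.dopl, "masked": trace.mask,
            }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["cone_id", "trial_id", "t_s", "dopl_nm", "masked"])
    return df, exclusions
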