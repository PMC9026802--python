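"""Baseline T1/M0 estimation and signal-to-concentration conversion.

The dynamic series is a spoiled gradient echo (SPGR). Its steady-state signal

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1)

links signal to the longitudinal relaxation time T1. Two pre-contrast
acquisitions at different flip angles determine (T1_0, M0) exactly
(two-point DESPOT1). During contrast passage the agent shortens T1 via

    1 / T1(t) = 1 / T1_0 + r1 * C(t)

so inverting the SPGR equation frame by frame yields the gadolinium
concentration C(t) in mM.

Assumptions: the dynamic frames are acquired at the higher flip angle;
T2*/echo-time effects are neglected (TE = 2 ms is short against tissue T2*);
no B1 correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelaxometryFit:
    """Baseline relaxometry: T1_0 in ms and equilibrium signal scale M0."""

    t10_ms: float
    m0: float

    def __post_init__(self) -> None:
        if self.t10_ms <= 0 or self.m0 <= 0:
            raise ValueError("T1_0 and M0 must be positive")


@dataclass(frozen=True)
class SignalCurve:
    """Dynamic signal samples at a single flip angle."""

    times_s: np.ndarray
    values: np.ndarray
    flip_deg: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ConcentrationCurve:
    """Gadolinium concentration samples, mM."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)


def spgr_signal(m0, t1_ms, flip_deg, tr_ms):
    """Closed-form SPGR steady-state signal.

    Vectorized over any argument; ``t1_ms`` must be positive and the flip
    angle strictly inside (0, 90) degrees.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if not (0.0 < float(flip_deg) < 90.0):
        raise ValueError("flip angle must lie in (0, 90) degrees")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


class DualFlipError(ValueError):
    """Raised when a flip-angle signal pair admits no SPGR solution."""


def fit_t1_dual_flip(s_low: float, s_high: float, acq: AcquisitionParams) -> RelaxometryFit:
    """Solve (T1_0, M0) exactly from signals at the two calibration flips.

    Linearizes the SPGR equation: with y = S/sin(a) and x = S/tan(a) the two
    points lie on y = E1*x + M0*(1-E1), so E1 is the slope through them.
    Raises :class:`DualFlipError` when the implied E1 falls outside (0, 1)
    (no physical T1 reproduces the pair).
    """
    if s_low <= 0 or s_high <= 0:
        raise DualFlipError("both signals must be positive")
    a_lo = np.deg2rad(acq.flip_low_deg)
    a_hi = np.deg2rad(acq.flip_high_deg)
    x = np.array([s_low / np.tan(a_lo), s_high / np.tan(a_hi)])
    y = np.array([s_low / np.sin(a_lo), s_high / np.sin(a_hi)])
    dx = x[0] - x[1]
    if dx == 0:
        raise DualFlipError("degenerate pair: identical abscissae")
    e1 = (y[0] - y[1]) / dx
    if not (0.0 < e1 < 1.0):
        raise DualFlipError(f"implied E1={e1:.6g} outside (0, 1)")
    t10 = -acq.tr_ms / np.log(e1)
    m0 = (y[0] - e1 * x[0]) / (1.0 - e1)
    if m0 <= 0:
        raise DualFlipError(f"implied M0={m0:.6g} not positive")
    return RelaxometryFit(t10_ms=float(t10), m0=float(m0))


def _invert_spgr_to_r1(values: np.ndarray, m0: float, flip_deg: float, tr_ms: float) -> np.ndarray:
    """Per-frame SPGR inversion to R1 = 1/T1 (ms^-1); NaN where not invertible."""
    a = np.deg2rad(flip_deg)
    sa, ca = np.sin(a), np.cos(a)
    s = np.asarray(values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * sa - s) / (m0 * sa - s * ca)
    bad = ~np.isfinite(e1) | (e1 <= 0.0) | (e1 >= 1.0)
    e1 = np.where(bad, 0.5, e1)  # placeholder, masked below
    r1 = -np.log(e1) / tr_ms
    r1[bad] = np.nan
    return r1


def concentration_from_signal(
    curve: SignalCurve,
    fit: RelaxometryFit,
    acq: AcquisitionParams,
    n_baseline: int = 1,
) -> ConcentrationCurve:
    """Convert a dynamic SPGR signal curve to gadolinium concentration (mM).

    The equilibrium scale is re-anchored on the mean of the ``n_baseline``
    pre-contrast frames so that baseline concentration is exactly zero at the
    fitted T1_0 (this absorbs any gain difference between the calibration and
    dynamic acquisitions). Frames whose signal cannot be inverted (at or above
    the SPGR saturation ceiling) are returned as NaN and logged.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if curve.values.size < n_baseline:
        raise ValueError("curve shorter than n_baseline")
    flip = curve.flip_deg
    baseline = float(np.mean(curve.values[:n_baseline]))
    if baseline <= 0:
        raise ValueError("non-positive baseline signal")
    # m0 such that spgr_signal(m0, t10, flip) == baseline mean
    unit = spgr_signal(1.0, fit.t10_ms, flip, acq.tr_ms)
    m0_dyn = baseline / unit
    r1 = _invert_spgr_to_r1(curve.values, m0_dyn, flip, acq.tr_ms)
    n_bad = int(np.sum(~np.isfinite(r1)))
    if n_bad:
        logger.warning("%d/%d frames not invertible (saturation); set to NaN", n_bad, r1.size)
    # r1 in ms^-1 -> s^-1 (x1000); relaxivity in L mmol^-1 s^-1 -> C in mM
    conc = (r1 - 1.0 / fit.t10_ms) * 1000.0 / acq.r1_relaxivity
    return ConcentrationCurve(times_s=curve.times_s, values=conc)


def aif_from_blood(c_blood, hematocrit: float):
    """Whole-blood to plasma concentration: C_p = C_blood / (1 - Hct)."""
    if not (0.0 <= hematocrit < 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")
    return np.asarray(c_blood, dtype=float) / (1.0 - hematocrit)
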