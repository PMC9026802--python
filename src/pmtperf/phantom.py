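"""4D DCE-MRI digital phantoms with known ground-truth kinetics.

A phantom is a small voxel grid holding labelled box regions: an arterial
region whose concentration follows the (blood-corrected) input function,
and tumor regions whose concentration follows the extended Tofts forward
model. Concentration is mapped to SPGR signal through the acquisition
parameters (1/T1(t) = 1/T1_0 + r1 C(t)), producing the dynamic series at
the high flip angle plus the two pre-contrast calibration volumes the
relaxometry stage needs. With zero noise the full analysis chain
(relaxometry -> concentration -> Tofts fit) recovers the ground truth,
which is the phantom's purpose; anatomy, motion and coil effects are out
of scope. Noise is additive Gaussian on the magnitude signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .acquisition import AcquisitionParams
from .aif import AifParams, ArterialInputFunction
from .relaxometry import SignalCurve, spgr_signal
from .tofts import TissueKinetics, tofts_forward

AORTA_LABEL_NAME = "aorta"


@dataclass(frozen=True)
class RegionSpec:
    """One labelled box region.

    ``kinetics=None`` marks the arterial region (concentration = whole-blood
    input); otherwise the region is tissue with the given kinetics. ``box``
    is ((x0, x1), (y0, y1), (z0, z1)) in voxel indices, stop-exclusive.
    """

    label: int
    name: str
    box: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]
    t10_ms: float
    m0: float = 1000.0
    kinetics: Optional[TissueKinetics] = None

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("region labels must be positive (0 is background)")
        if self.t10_ms <= 0 or self.m0 <= 0:
            raise ValueError("T1_0 and M0 must be positive")
        for lo, hi in self.box:
            if hi <= lo or lo < 0:
                raise ValueError("box bounds must satisfy 0 <= lo < hi")

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int] = (16, 16, 4)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 5.0)
    frame_spacing_s: float = 2.5
    duration_s: float = 204.0
    regions: Tuple[RegionSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    aif_params: AifParams = field(default_factory=AifParams)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid dimensions must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.frame_spacing_s <= 0 or self.duration_s <= 0:
            raise ValueError("frame spacing and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def n_frames(self) -> int:
        """floor(duration / spacing) + 1, including the t = 0 frame."""
        return int(self.duration_s / self.frame_spacing_s) + 1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_spacing_s


def default_two_region_spec(
    kinetics: Optional[TissueKinetics] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A compact aorta + tumor phantom with protocol-default timing."""
    kin = kinetics or TissueKinetics.from_rates(ktrans=0.2, kep=1.0, vp=0.02)
    regions = (
        RegionSpec(label=1, name="tumor", box=((2, 8), (2, 8), (0, 4)),
                   t10_ms=1200.0, kinetics=kin),
        RegionSpec(label=2, name=AORTA_LABEL_NAME, box=((10, 14), (10, 14), (0, 4)),
                   t10_ms=1700.0, kinetics=None),
    )
    return PhantomSpec(regions=regions, noise_sd=noise_sd, seed=seed)


@dataclass
class Phantom:
    """Simulated acquisition plus its generating ground truth."""

    dynamic: np.ndarray  # (nx, ny, nz, nt) signal at flip_high
    calib_low: np.ndarray  # (nx, ny, nz) pre-contrast at flip_low
    calib_high: np.ndarray  # (nx, ny, nz) pre-contrast at flip_high
    mask: np.ndarray  # (nx, ny, nz) integer region labels
    times_s: np.ndarray
    aif: ArterialInputFunction
    spec: PhantomSpec
    acq: AcquisitionParams
    truth: Dict[int, dict]

    def roi_mean_curve(self, label: int) -> SignalCurve:
        """Mean dynamic signal over the labelled region, per frame."""
        sel = self.mask == label
        if not np.any(sel):
            raise ValueError(f"no voxels with label {label}")
        vals = self.dynamic[sel].mean(axis=0)
        return SignalCurve(times_s=self.times_s, values=vals,
                           flip_deg=self.acq.flip_high_deg)

    def roi_mean_calibration(self, label: int) -> Tuple[float, float]:
        """Mean pre-contrast signal at (flip_low, flip_high) over the region."""
        sel = self.mask == label
        if not np.any(sel):
            raise ValueError(f"no voxels with label {label}")
        return float(self.calib_low[sel].mean()), float(self.calib_high[sel].mean())

    def aorta_label(self) -> int:
        for r in self.spec.regions:
            if r.kinetics is None:
                return r.label
        raise ValueError("phantom has no arterial region")

    def tumor_labels(self) -> Tuple[int, ...]:
        return tuple(r.label for r in self.spec.regions if r.kinetics is not None)


def make_phantom(spec: PhantomSpec, acq: Optional[AcquisitionParams] = None) -> Phantom:
    """Forward-simulate the phantom described by ``spec``.

    Rejects overlapping region boxes. The ground-truth record stores each
    region's kinetics, T1_0, M0 and its noiseless concentration curve,
    plus the plasma input function.
    """
    acq = acq or AcquisitionParams(frame_spacing_s=spec.frame_spacing_s,
                                   duration_s=spec.duration_s)
    if not spec.regions:
        raise ValueError("phantom needs at least one region")
    times = spec.frame_times()
    mask = np.zeros(spec.shape, dtype=np.int16)
    for r in spec.regions:
        sl = r.slices
        for (lo, hi), n in zip(r.box, spec.shape):
            if hi > n:
                raise ValueError(f"region '{r.name}' exceeds the grid")
        if np.any(mask[sl] != 0):
            raise ValueError(f"region '{r.name}' overlaps another region")
        mask[sl] = r.label

    aif = ArterialInputFunction.parametric(times, spec.aif_params)
    rng = np.random.default_rng(spec.seed)
    nt = times.size
    dynamic = np.zeros(spec.shape + (nt,))
    calib_low = np.zeros(spec.shape)
    calib_high = np.zeros(spec.shape)
    truth: Dict[int, dict] = {}

    for r in spec.regions:
        if r.kinetics is None:
            conc = aif.cp_mM * (1.0 - acq.hematocrit)  # whole-blood concentration
            kin_record = None
        else:
            conc = tofts_forward(r.kinetics, aif).values
            kin_record = r.kinetics.as_dict()
        # 1/T1(t) in ms^-1; relaxivity converts mM to s^-1, hence /1000
        r1_t = 1.0 / r.t10_ms + acq.r1_relaxivity * conc / 1000.0
        sig = spgr_signal(r.m0, 1.0 / r1_t, acq.flip_high_deg, acq.tr_ms)
        sel = mask == r.label
        dynamic[sel] = sig
        calib_low[sel] = spgr_signal(r.m0, r.t10_ms, acq.flip_low_deg, acq.tr_ms)
        calib_high[sel] = spgr_signal(r.m0, r.t10_ms, acq.flip_high_deg, acq.tr_ms)
        truth[r.label] = {
            "name": r.name,
            "t10_ms": r.t10_ms,
            "m0": r.m0,
            "kinetics": kin_record,
            "concentration_mM": conc.tolist(),
        }

    if spec.noise_sd > 0:
        fg = mask > 0
        dynamic[fg] += rng.normal(0.0, spec.noise_sd, size=dynamic[fg].shape)
        calib_low[fg] += rng.normal(0.0, spec.noise_sd, size=calib_low[fg].shape)
        calib_high[fg] += rng.normal(0.0, spec.noise_sd, size=calib_high[fg].shape)

    truth_meta = {
        "aif_times_s": times.tolist(),
        "aif_cp_mM": aif.cp_mM.tolist(),
        "hematocrit": acq.hematocrit,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    truth[0] = truth_meta  # background slot carries run-level ground truth
    return Phantom(
        dynamic=dynamic, calib_low=calib_low, calib_high=calib_high,
        mask=mask, times_s=times, aif=aif, spec=spec, acq=acq, truth=truth,
    )
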