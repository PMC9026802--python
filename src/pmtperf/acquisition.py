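"""Acquisition protocol parameters for the dynamic contrast-enhanced series.

Defaults mirror a 3 T chest DCE protocol: 3D spoiled gradient echo with
TR = 4 ms, dual calibration flip angles 5 deg / 15 deg, one dynamic frame every
2.5 s for 3 min 24 s, gadobutrol at 0.1 mmol/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner and contrast-agent settings shared across the pipeline.

    Parameters
    ----------
    tr_ms : repetition time of the spoiled gradient echo readout, ms.
    flip_low_deg, flip_high_deg : calibration flip angles, degrees. The
        dynamic series is assumed acquired at ``flip_high_deg``.
    frame_spacing_s : time between dynamic frames, s.
    duration_s : total dynamic acquisition duration, s.
    r1_relaxivity : longitudinal relaxivity of the contrast agent at the
        field strength used, L mmol^-1 s^-1. Default 5.0 (gadobutrol, 3 T).
    hematocrit : large-vessel hematocrit used to convert whole-blood to
        plasma concentration at the arterial input. Default 0.42.
    dose_mmol_per_kg : injected dose, mmol per kg body weight.
    """

    tr_ms: float = 4.0
    flip_low_deg: float = 5.0
    flip_high_deg: float = 15.0
    frame_spacing_s: float = 2.5
    duration_s: float = 204.0  # 3 min 24 s
    r1_relaxivity: float = 5.0
    hematocrit: float = 0.42
    dose_mmol_per_kg: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_low_deg < self.flip_high_deg < 90.0):
            raise ValueError(
                "flip angles must satisfy 0 < flip_low < flip_high < 90 deg"
            )
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.r1_relaxivity <= 0:
            raise ValueError("r1_relaxivity must be positive")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.frame_spacing_s <= 0 or self.duration_s <= 0:
            raise ValueError("frame spacing and duration must be positive")

    @property
    def n_frames(self) -> int:
        """Dynamic frame count: floor(duration / spacing) + 1, including t=0."""
        return int(self.duration_s / self.frame_spacing_s) + 1

    def frame_times(self):
        import numpy as np

        return np.arange(self.n_frames, dtype=float) * self.frame_spacing_s

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)
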