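"""Acquisition metadata for single-voxel short-echo STEAM spectroscopy."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio over 2*pi, MHz per tesla.
GAMMA_H_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class AcquisitionParams:
    """Parameters of a single-voxel STEAM acquisition at ultra-high field.

    Defaults describe a 7 T short-echo protocol: TE 11 ms, TR 5 s,
    64 transients, a 15 mm isotropic voxel, and the ppm axis referenced to
    water at 4.65 ppm.
    """

    field_strength: float = 7.0
    spectrometer_freq: float | None = None  # MHz; derived from field if None
    te_ms: float = 11.0
    tr_s: float = 5.0
    n_transients: int = 64
    sweep_width_ppm: float = 12.0
    n_points: int = 4096
    voxel_volume_mm3: float = 3375.0  # 15 x 15 x 15
    ppm_reference: float = 4.65  # water

    def __post_init__(self) -> None:
        if self.spectrometer_freq is None:
            object.__setattr__(
                self, "spectrometer_freq", GAMMA_H_MHZ_PER_T * self.field_strength
            )
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.n_points < 256:
            raise ValueError("n_points must be at least 256")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be positive")
        nominal = GAMMA_H_MHZ_PER_T * self.field_strength
        if abs(self.spectrometer_freq - nominal) > 0.005 * nominal:
            raise ValueError(
                f"spectrometer_freq {self.spectrometer_freq} MHz inconsistent with "
                f"field strength {self.field_strength} T (expected ~{nominal:.1f})"
            )

    @property
    def ppm_axis(self) -> np.ndarray:
        """Ascending ppm grid centred on the reference frequency."""
        half = self.sweep_width_ppm / 2.0
        return np.linspace(
            self.ppm_reference - half, self.ppm_reference + half, self.n_points
        )

    @property
    def hz_per_ppm(self) -> float:
        return float(self.spectrometer_freq)

    @property
    def ppm_step(self) -> float:
        return self.sweep_width_ppm / (self.n_points - 1)

    def to_dict(self) -> dict:
        return {
            "field_strength": self.field_strength,
            "spectrometer_freq": self.spectrometer_freq,
            "te_ms": self.te_ms,
            "tr_s": self.tr_s,
            "n_transients": self.n_transients,
            "sweep_width_ppm": self.sweep_width_ppm,
            "n_points": self.n_points,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "ppm_reference": self.ppm_reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)
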