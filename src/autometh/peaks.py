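"""Centroided peak lists (MS1 fingerprints and MS2 CID spectra)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class PeakList:
    """A centroided spectrum: parallel m/z and intensity arrays plus metadata.

    Peaks are kept sorted ascending by m/z. ``ms_level`` is 1 for a
    fingerprint spectrum, 2 for a fragmentation spectrum; precursor fields
    are required at level 2 and forbidden at level 1.
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    title: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InputError("mz and intensity must be 1-d arrays of equal length")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be >= 0")
        if self.ms_level not in (1, 2):
            raise InputError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise InputError("MS2 peak list requires precursor_mz")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)
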