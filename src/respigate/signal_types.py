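"""Shared containers for respiratory traces and their phase series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Accepted modality labels. ``latent`` marks the noise-free unit-amplitude
#: breathing process both sensors observe.
MODALITIES = ("camera", "navigator", "latent")


@dataclass
class RespiratorySignal:
    """A timestamped respiratory amplitude trace.

    Parameters
    ----------
    t:
        Sample times in seconds, strictly increasing and uniform.
    y:
        Amplitudes: arbitrary units for camera traces, millimetres for
        navigator traces.
    fs:
        Nominal sampling rate in Hz (camera 20, navigator 2 by default).
    modality:
        One of ``camera``, ``navigator`` or ``latent``.
    subject_id:
        Free-form subject label.
    """

    t: np.ndarray
    y: np.ndarray
    fs: float
    modality: str = "camera"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1:
            raise ValueError("t and y must be one-dimensional")
        if len(self.t) != len(self.y):
            raise ValueError(
                f"length mismatch: {len(self.t)} times vs {len(self.y)} amplitudes"
            )
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("sample times must be uniform to within 1e-9 s")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trace length in seconds (first to last sample)."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def copy_with(self, y: np.ndarray) -> "RespiratorySignal":
        """Return a copy carrying new amplitudes on the same time base."""
        return RespiratorySignal(
            t=self.t.copy(), y=np.asarray(y, dtype=float),
            fs=self.fs, modality=self.modality, subject_id=self.subject_id,
        )


@dataclass
class PhaseSeries:
    """Per-sample respiratory phase bins with an acceptance mask.

    Bin 0 marks samples outside the first/last detected extremum
    (unassigned); bins 1-40 are inspiration, 41-100 expiration. A sample is
    accepted iff its bin lies inside ``accept_range`` (inclusive).
    """

    t: np.ndarray
    bin: np.ndarray
    accepted: np.ndarray
    fs: float
    n_bins: int = 100
    accept_range: tuple[int, int] = (41, 100)
    subject_id: str = ""
    modality: str = field(default="camera")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bin = np.asarray(self.bin, dtype=int)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if not (len(self.t) == len(self.bin) == len(self.accepted)):
            raise ValueError("t, bin and accepted must have equal length")
        if self.bin.size and (self.bin.min() < 0 or self.bin.max() > self.n_bins):
            raise ValueError(f"bins must lie in [0, {self.n_bins}]")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask of samples that fall inside a detected cycle."""
        return self.bin > 0

    @property
    def acceptance_fraction(self) -> float:
        """Accepted fraction among assigned samples (NaN if none assigned)."""
        n_assigned = int(self.assigned.sum())
        if n_assigned == 0:
            return float("nan")
        return float(self.accepted.sum() / n_assigned)
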