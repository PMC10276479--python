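"""Uniformly sampled intracranial-pressure trace container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

#: Allowed deviation of a timestamp from the uniform grid, in seconds.
TIME_UNIFORMITY_TOL = 1e-6


@dataclass
class PressureTrace:
    """A uniformly sampled pressure signal in mmHg.

    Parameters
    ----------
    t
        Sample times in seconds, starting at 0, on a uniform grid.
    p
        Pressure samples in mmHg. Invalid samples may hold NaN.
    fs
        Sampling rate in Hz.
    mask
        Per-sample validity: ``True`` where the sample is usable.
    """

    t: np.ndarray
    p: np.ndarray
    fs: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.p)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.fs <= 0:
            raise ContractError(f"sampling rate must be positive, got {self.fs}")
        if not (len(self.t) == len(self.p) == len(self.mask)):
            raise ContractError("t, p and mask must have equal length")
        if len(self.t) >= 2:
            grid = self.t[0] + np.arange(len(self.t)) / self.fs
            dev = np.max(np.abs(self.t - grid))
            if dev > TIME_UNIFORMITY_TOL:
                raise ContractError(
                    f"time axis deviates from uniform grid by {dev:.3g} s "
                    f"(tolerance {TIME_UNIFORMITY_TOL:g} s)"
                )

    @classmethod
    def from_samples(cls, p: np.ndarray, fs: float, mask: np.ndarray | None = None) -> "PressureTrace":
        p = np.asarray(p, dtype=float)
        t = np.arange(len(p)) / fs
        return cls(t=t, p=p, fs=fs, mask=mask)

    @property
    def n_samples(self) -> int:
        return len(self.p)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (span covered by the samples)."""
        return self.n_samples / self.fs

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.mask)) if self.n_samples else 0.0

    def copy(self) -> "PressureTrace":
        return PressureTrace(t=self.t.copy(), p=self.p.copy(), fs=self.fs, mask=self.mask.copy())
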