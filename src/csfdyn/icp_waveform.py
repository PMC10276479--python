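"""ICP waveform cleaning, baseline ICP and mean wave amplitude (MWA).

The processing chain mirrors the acquisition pipeline for epidural ICP
recordings sampled at ~1 kHz:

1. :func:`despike` — mask non-physiological samples and bridge short gaps;
2. :func:`antialias_downsample` — zero-phase low-pass and resample to 100 Hz;
3. :func:`bandpass_cardiac` — zero-phase spectral bandpass (default
   1.6–5.5 Hz) with Tukey-tapered band edges, isolating the cardiac
   component from ventilation (~1.3 Hz) and slow drift;
4. :func:`instantaneous_p2p` — per-cardiac-cycle peak-to-peak amplitudes.

:func:`mean_wave_amplitude` composes the four stages; the MWA is the mean of
the per-cycle amplitudes. :func:`baseline_icp` averages the trailing window
of the raw (cleaned) trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from ._trace import PressureTrace
from .errors import ContractError, UnusableTraceError

__all__ = [
    "PressureTrace",
    "DespikeResult",
    "CycleAmplitudes",
    "MWAResult",
    "despike",
    "antialias_downsample",
    "bandpass_cardiac",
    "instantaneous_p2p",
    "mean_wave_amplitude",
    "baseline_icp",
]

DEFAULT_BAND = (1.6, 5.5)
DEFAULT_FS_ANALYSIS = 100.0
#: Masked runs at most this long (seconds) are linearly bridged.
MAX_BRIDGE_S = 0.5
#: Seconds excluded at each end of the filtered trace before cycle extraction.
EDGE_EXCLUDE_S = 2.0


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

@dataclass
class DespikeResult:
    """Outcome of :func:`despike`.

    ``trace`` has short masked runs bridged (mask restored to True there);
    runs longer than :data:`MAX_BRIDGE_S` stay masked and split the trace
    into the valid ``segments`` (half-open sample-index ranges).
    """

    trace: PressureTrace
    n_masked: int
    n_bridged: int
    segments: list[tuple[int, int]] = field(default_factory=list)


def _runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``bad`` is True."""
    if not bad.any():
        return []
    d = np.diff(bad.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if bad[0]:
        starts.insert(0, 0)
    if bad[-1]:
        ends.append(len(bad))
    return list(zip(starts, ends))


def despike(trace: PressureTrace, max_abs: float = 50.0, max_jump: float = 5.0) -> DespikeResult:
    """Mask spikes and non-physiological samples.

    A sample is masked when ``|p| > max_abs`` (mmHg) or when the jump from
    the previous sample exceeds ``max_jump`` (mmHg per sample), in addition
    to any sample already invalid (e.g. non-numeric on read). Masked runs
    of at most 0.5 s are linearly bridged; longer runs remain masked and
    delimit the valid segments.

    Raises
    ------
    UnusableTraceError
        If more than 50% of samples are masked. A warning is emitted
        above 20%.
    """
    if max_abs <= 0 or max_jump <= 0:
        raise ContractError("despike thresholds must be positive")
    p = trace.p.copy()
    bad = ~trace.mask | ~np.isfinite(p) | (np.abs(p) > max_abs)
    if len(p) > 1:
        jump = np.abs(np.diff(np.where(np.isfinite(p), p, 0.0)))
        bad[1:] |= jump > max_jump
    n_masked = int(bad.sum())
    frac = n_masked / max(len(p), 1)
    if frac > 0.5:
        raise UnusableTraceError(f"{frac:.0%} of samples masked; trace unusable")
    if frac > 0.2:
        warnings.warn(f"{frac:.0%} of samples masked during despiking", stacklevel=2)

    max_bridge = int(round(MAX_BRIDGE_S * trace.fs))
    mask = ~bad
    n_bridged = 0
    for i0, i1 in _runs(bad):
        if i1 - i0 <= max_bridge:
            lo, hi = i0 - 1, i1  # neighbouring valid samples
            if lo < 0 and hi >= len(p):
                continue
            if lo < 0:
                p[i0:i1] = p[hi]
            elif hi >= len(p):
                p[i0:i1] = p[lo]
            else:
                p[i0:i1] = np.interp(np.arange(i0, i1), [lo, hi], [p[lo], p[hi]])
            mask[i0:i1] = True
            n_bridged += i1 - i0
    p[~mask] = np.nan
    segments = _runs(mask)
    out = PressureTrace(t=trace.t.copy(), p=p, fs=trace.fs, mask=mask)
    return DespikeResult(trace=out, n_masked=n_masked, n_bridged=n_bridged, segments=segments)


# ---------------------------------------------------------------------------
# anti-alias downsampling
# ---------------------------------------------------------------------------

def antialias_downsample(trace: PressureTrace, fs_out: float = DEFAULT_FS_ANALYSIS) -> PressureTrace:
    """Low-pass filter and resample to ``fs_out``.

    The anti-alias filter is a linear-phase Kaiser-window FIR with passband
    edge ``0.4*fs_out`` and stopband edge ``0.5*fs_out`` designed for 80 dB
    stopband attenuation; applied polyphase with the group delay
    compensated, so the stage is effectively zero-phase.
    """
    if fs_out >= trace.fs:
        raise ContractError(f"fs_out ({fs_out} Hz) must be below trace fs ({trace.fs} Hz)")
    ratio = Fraction(fs_out / trace.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator

    fs_up = trace.fs * up
    pass_edge = 0.4 * fs_out
    stop_edge = 0.5 * fs_out
    numtaps, beta = signal.kaiserord(80.0, (stop_edge - pass_edge) / (0.5 * fs_up))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    taps = signal.firwin(numtaps, (pass_edge + stop_edge) / 2, window=("kaiser", beta), fs=fs_up)

    p_in = np.where(trace.mask, trace.p, 0.0)
    if not trace.mask.all():
        # fill unmasked gaps by interpolation so the FIR does not smear NaN
        idx = np.flatnonzero(trace.mask)
        if idx.size == 0:
            raise UnusableTraceError("no valid samples to downsample")
        p_in = np.interp(np.arange(len(p_in)), idx, trace.p[idx])
    p_out = signal.resample_poly(p_in, up, down, window=taps * up, padtype="line")
    t_out = np.arange(len(p_out)) / fs_out
    mask_out = np.interp(t_out, trace.t - trace.t[0], trace.mask.astype(float)) > 0.5
    return PressureTrace(t=t_out, p=p_out, fs=fs_out, mask=mask_out)


# ---------------------------------------------------------------------------
# spectral bandpass
# ---------------------------------------------------------------------------

def _band_gain(freqs: np.ndarray, f_lo: float, f_hi: float, taper_fraction: float) -> np.ndarray:
    """Bandpass gain with raised-cosine (Tukey-profile) edges.

    Each edge ramp is centred on the band edge and spans
    ``taper_fraction*(f_hi-f_lo)/2`` so the nominal edge sits at half gain.
    """
    half = taper_fraction * (f_hi - f_lo) / 2.0
    gain = np.zeros_like(freqs)
    flat = (freqs >= f_lo + half / 2) & (freqs <= f_hi - half / 2)
    gain[flat] = 1.0
    if half > 0:
        lo_ramp = (freqs > f_lo - half / 2) & (freqs < f_lo + half / 2)
        x = (freqs[lo_ramp] - (f_lo - half / 2)) / half
        gain[lo_ramp] = 0.5 * (1 - np.cos(np.pi * x))
        hi_ramp = (freqs > f_hi - half / 2) & (freqs < f_hi + half / 2)
        x = (freqs[hi_ramp] - (f_hi - half / 2)) / half
        gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * x))
    return gain


def bandpass_cardiac(
    trace: PressureTrace,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    taper_fraction: float = 0.25,
) -> PressureTrace:
    """Zero-phase spectral bandpass isolating the cardiac component.

    The signal (mean removed) is transformed to the frequency domain,
    multiplied by a band mask whose edges are tapered with a raised-cosine
    (Tukey) profile, and transformed back. With the defaults the ~1.3 Hz
    ventilation component is fully rejected while 2–5 Hz cardiac content
    passes at unit gain.
    """
    if not (0 < f_lo < f_hi < trace.fs / 2):
        raise ContractError(f"band ({f_lo}, {f_hi}) must satisfy 0 < f_lo < f_hi < fs/2")
    if trace.duration < 10.0 / f_lo:
        raise ContractError(
            f"trace of {trace.duration:.1f} s too short for f_lo={f_lo} Hz "
            f"(need >= {10.0 / f_lo:.1f} s)"
        )
    p = np.where(trace.mask, trace.p, np.nanmean(trace.p[trace.mask]))
    p = p - p.mean()
    spec = np.fft.rfft(p)
    freqs = np.fft.rfftfreq(len(p), d=1.0 / trace.fs)
    spec *= _band_gain(freqs, f_lo, f_hi, taper_fraction)
    out = np.fft.irfft(spec, n=len(p))
    return PressureTrace(t=trace.t.copy(), p=out, fs=trace.fs, mask=trace.mask.copy())


# ---------------------------------------------------------------------------
# per-cycle peak-to-peak
# ---------------------------------------------------------------------------

@dataclass
class CycleAmplitudes:
    """Per-cardiac-cycle peak-to-peak amplitudes (mmHg)."""

    amplitudes: np.ndarray
    cycle_start_t: np.ndarray
    n_discarded: int


def instantaneous_p2p(
    filtered: PressureTrace,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    edge_exclude: float = EDGE_EXCLUDE_S,
    min_cycles: int = 10,
) -> CycleAmplitudes:
    """Peak-to-peak amplitude per cardiac cycle of a band-limited signal.

    Cycles are delimited by successive positive-going zero crossings; each
    cycle's amplitude is its max minus min. Cycles whose period falls
    outside [1/f_hi, 1/f_lo] are discarded (and counted). The first and
    last ``edge_exclude`` seconds are ignored (filter transients).
    """
    p = filtered.p
    t = filtered.t
    lo = t[0] + edge_exclude
    hi = t[-1] - edge_exclude
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 2:
        raise ContractError("trace too short after edge exclusion")
    p = p[sel]
    t = t[sel]
    if np.ptp(p) < 1e-10:  # below any sensor resolution: no pulsation present
        raise ContractError("filtered signal is flat; no cardiac cycles")
    crossings = np.flatnonzero((p[:-1] <= 0) & (p[1:] > 0))
    if crossings.size < 2:
        raise ContractError("no cardiac cycles found (fewer than 2 zero crossings)")
    amps, starts = [], []
    n_discarded = 0
    min_period, max_period = 1.0 / f_hi, 1.0 / f_lo
    for a, b in zip(crossings[:-1], crossings[1:]):
        period = t[b] - t[a]
        if not (min_period <= period <= max_period):
            n_discarded += 1
            continue
        seg = p[a : b + 1]
        amps.append(seg.max() - seg.min())
        starts.append(t[a])
    if len(amps) < min_cycles:
        raise ContractError(f"only {len(amps)} valid cycles (< {min_cycles})")
    return CycleAmplitudes(
        amplitudes=np.asarray(amps), cycle_start_t=np.asarray(starts), n_discarded=n_discarded
    )


# ---------------------------------------------------------------------------
# composed MWA
# ---------------------------------------------------------------------------

@dataclass
class MWAResult:
    """Mean wave amplitude of an ICP recording."""

    mwa: float
    amplitudes: np.ndarray
    band: tuple[float, float]
    fs_analysis: float
    n_cycles: int
    n_discarded: int
    n_masked: int
    method: str = "cycle"

    @property
    def params(self) -> dict:
        return {
            "band_hz": list(self.band),
            "fs_analysis_hz": self.fs_analysis,
            "method": self.method,
        }


def mean_wave_amplitude(
    raw: PressureTrace,
    *,
    band: tuple[float, float] = DEFAULT_BAND,
    fs_analysis: float = DEFAULT_FS_ANALYSIS,
    max_abs: float = 50.0,
    max_jump: float = 5.0,
    taper_fraction: float = 0.25,
    method: str = "cycle",
    min_duration: float = 60.0,
) -> MWAResult:
    """Mean wave amplitude via despike → downsample → bandpass → per-cycle p2p.

    ``method`` selects the amplitude estimator: ``"cycle"`` (default,
    per-cycle max−min) or ``"envelope"`` (2× the Hilbert envelope, averaged
    over the same interior region); the two agree within ~5% on
    sinusoid-like pulses.
    """
    if raw.duration < min_duration:
        raise ContractError(
            f"trace of {raw.duration:.1f} s below minimum {min_duration:.0f} s for MWA"
        )
    cleaned = despike(raw, max_abs=max_abs, max_jump=max_jump)
    ds = antialias_downsample(cleaned.trace, fs_out=fs_analysis)
    filt = bandpass_cardiac(ds, band[0], band[1], taper_fraction=taper_fraction)
    if method == "cycle":
        cyc = instantaneous_p2p(filt, f_lo=band[0], f_hi=band[1])
        amps = cyc.amplitudes
        n_discarded = cyc.n_discarded
    elif method == "envelope":
        env = 2.0 * np.abs(signal.hilbert(filt.p))
        sel = (filt.t >= filt.t[0] + EDGE_EXCLUDE_S) & (filt.t <= filt.t[-1] - EDGE_EXCLUDE_S)
        amps = env[sel]
        n_discarded = 0
    else:
        raise ContractError(f"unknown MWA method {method!r}")
    return MWAResult(
        mwa=float(np.mean(amps)),
        amplitudes=amps,
        band=band,
        fs_analysis=fs_analysis,
        n_cycles=len(amps),
        n_discarded=n_discarded,
        n_masked=cleaned.n_masked,
        method=method,
    )


def baseline_icp(trace: PressureTrace, window: float = 900.0) -> float:
    """Mean ICP (mmHg) over the trailing ``window`` seconds of valid samples."""
    if window <= 0:
        raise ContractError("window must be positive")
    if trace.duration < window:
        warnings.warn(
            f"trace ({trace.duration:.0f} s) shorter than baseline window "
            f"({window:.0f} s); using full trace",
            stacklevel=2,
        )
        window = trace.duration
    sel = trace.t >= trace.t[-1] - window + 1.0 / trace.fs
    valid = sel & trace.mask & np.isfinite(trace.p)
    if not valid.any():
        raise UnusableTraceError("no valid samples in baseline window")
    return float(np.mean(trace.p[valid]))
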