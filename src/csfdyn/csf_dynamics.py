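"""CSF outflow resistance, secretion rate, dye-dispersion flow and brain water.

Four independent estimators:

* constant-rate infusion → outflow resistance ``R_out = (ICP_f − ICP_i)/I``
  per step, averaged across infusion rates;
* ventriculo-cisternal dye dilution → secretion rate
  ``Vp = r_i (C_i − C_o)/C_o`` averaged over the steady tail window;
* normalized dye-intensity time series → flow-rate slope by OLS over an
  early window;
* wet/dry brain masses → water percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._trace import PressureTrace
from .errors import ContractError

__all__ = [
    "InfusionStep",
    "InfusionStudy",
    "RoutResult",
    "PerfusionSample",
    "PerfusionRun",
    "VpResult",
    "DyeSeries",
    "DyeFlowResult",
    "BrainWaterPair",
    "PlateauEstimate",
    "compute_rout_step",
    "compute_rout_study",
    "plateau_estimate",
    "compute_vp",
    "vp_timecourse",
    "dye_flow_rate",
    "brain_water_percent",
]

DEFAULT_INFUSION_RATES = (5.0, 10.0, 15.0, 20.0)  # µl/min
DEFAULT_STEP_DURATION_MIN = 10.0
DEFAULT_PAUSE_MIN = 1.0


# ---------------------------------------------------------------------------
# outflow resistance
# ---------------------------------------------------------------------------

@dataclass
class InfusionStep:
    rate: float      # µl/min
    plateau: float   # mmHg, stable ICP at end of step
    stable: bool = True


@dataclass
class InfusionStudy:
    """Baseline ICP plus ordered constant-rate infusion steps."""

    icp_i: float
    steps: list[InfusionStep]
    step_duration_min: float = DEFAULT_STEP_DURATION_MIN
    pause_min: float = DEFAULT_PAUSE_MIN

    def __post_init__(self) -> None:
        rates = [s.rate for s in self.steps]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ContractError(f"infusion rates must be strictly increasing, got {rates}")
        if self.icp_i < 0:
            raise ContractError("baseline ICP must be non-negative")


@dataclass
class RoutResult:
    per_step: list[float]            # mmHg·min/µl
    mean_rout: float
    n_steps: int
    mean_rout_stable: float | None = None   # mean over stable steps only
    flags: list[str] = field(default_factory=list)


def compute_rout_step(icp_i: float, icp_f: float, rate: float) -> float:
    """R_out for one step: ``(ICP_f − ICP_i)/I`` in mmHg·min/µl."""
    if rate <= 0:
        raise ContractError(f"infusion rate must be positive, got {rate}")
    return (icp_f - icp_i) / rate


def compute_rout_study(study: InfusionStudy) -> RoutResult:
    """Per-step R_out against the single pre-infusion baseline, averaged.

    Plateaus below baseline produce negative per-step values which are
    flagged but included in the mean. A second mean restricted to steps
    whose plateau was judged stable is also reported.
    """
    if not study.steps:
        raise ContractError("infusion study has no steps")
    per_step = [compute_rout_step(study.icp_i, s.plateau, s.rate) for s in study.steps]
    flags = []
    for s, r in zip(study.steps, per_step):
        if r < 0:
            flags.append(f"negative R_out at {s.rate} µl/min")
        if not s.stable:
            flags.append(f"unstable plateau at {s.rate} µl/min")
    stable_vals = [r for s, r in zip(study.steps, per_step) if s.stable]
    return RoutResult(
        per_step=per_step,
        mean_rout=float(np.mean(per_step)),
        n_steps=len(per_step),
        mean_rout_stable=float(np.mean(stable_vals)) if stable_vals else None,
        flags=flags,
    )


@dataclass
class PlateauEstimate:
    value: float          # mmHg
    stable: bool
    trend_mmhg_per_min: float


def plateau_estimate(
    trace: PressureTrace,
    step_start: float,
    step_duration: float,
    tail_fraction: float = 0.2,
    trend_limit: float = 0.5,
) -> PlateauEstimate:
    """Plateau ICP from an infusion step within a pressure trace.

    Averages the final ``tail_fraction`` of the step window; the stability
    flag is cleared when the linear trend over that window exceeds
    ``trend_limit`` mmHg/min.
    """
    t0 = step_start + step_duration * (1.0 - tail_fraction)
    t1 = step_start + step_duration
    if t0 < trace.t[0] - 1e-9 or t1 > trace.t[-1] + 1.0 / trace.fs + 1e-9:
        raise ContractError(
            f"step window [{t0:.1f}, {t1:.1f}] s outside trace span "
            f"[{trace.t[0]:.1f}, {trace.t[-1]:.1f}] s"
        )
    sel = (trace.t >= t0) & (trace.t <= t1) & trace.mask & np.isfinite(trace.p)
    if sel.sum() < 2:
        raise ContractError("no valid samples in plateau window")
    tt, pp = trace.t[sel], trace.p[sel]
    slope = float(stats.linregress(tt, pp).slope) * 60.0  # mmHg/s -> mmHg/min
    return PlateauEstimate(
        value=float(np.mean(pp)),
        stable=abs(slope) <= trend_limit,
        trend_mmhg_per_min=slope,
    )


# ---------------------------------------------------------------------------
# ventriculo-cisternal perfusion
# ---------------------------------------------------------------------------

@dataclass
class PerfusionSample:
    t: float                         # min from perfusion start
    co_triplicate: tuple[float, float, float]


@dataclass
class PerfusionRun:
    """One ventriculo-cisternal perfusion experiment."""

    ci_triplicate: tuple[float, float, float]
    samples: list[PerfusionSample]
    ri: float = 9.0                  # µl/min
    steady_window: float = 30.0      # final minutes used for Vp

    def __post_init__(self) -> None:
        if self.ri <= 0:
            raise ContractError("infusion rate ri must be positive")
        if any(v <= 0 for v in self.ci_triplicate):
            raise ContractError("inflow fluorescence replicates must be positive")
        times = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ContractError("sample times must be strictly increasing")


@dataclass
class VpResult:
    vp_per_sample: list[float]       # µl/min, all samples
    vp: float                        # mean over steady window
    window_used: float               # min
    n_in_window: int
    flags: list[str] = field(default_factory=list)


def compute_vp(ri: float, ci: float, co: float) -> float:
    """Secretion rate ``Vp = ri (Ci − Co)/Co`` in µl/min."""
    if co <= 0:
        raise ContractError(f"outflow fluorescence must be positive, got {co}")
    if ci <= 0:
        raise ContractError(f"inflow fluorescence must be positive, got {ci}")
    if ri <= 0:
        raise ContractError(f"infusion rate must be positive, got {ri}")
    return ri * (ci - co) / co


def _mean_triplicate(rep: tuple[float, float, float], flags: list[str], label: str) -> float:
    arr = np.asarray(rep, dtype=float)
    med = np.median(arr)
    mad = stats.median_abs_deviation(arr, scale="normal")
    if mad > 0 and np.any(np.abs(arr - med) > 3 * mad):
        flags.append(f"replicate outlier in {label}: {rep}")
    return float(arr.mean())


def vp_timecourse(run: PerfusionRun) -> VpResult:
    """Vp per sample and its mean over the final steady window.

    Triplicate fluorescence readings are averaged before Vp is computed;
    a replicate more than 3 robust SDs from its siblings is flagged, not
    dropped. Negative per-sample Vp values (outflow above inflow) are
    retained and flagged.
    """
    flags: list[str] = []
    ci = _mean_triplicate(run.ci_triplicate, flags, "Ci")
    t_end = run.samples[-1].t if run.samples else 0.0
    w0 = t_end - run.steady_window
    vp_all: list[float] = []
    in_window: list[float] = []
    for s in run.samples:
        co = _mean_triplicate(s.co_triplicate, flags, f"Co@{s.t:g}min")
        vp = compute_vp(run.ri, ci, co)
        if vp < 0:
            flags.append(f"negative Vp {vp:.3g} at t={s.t:g} min")
        vp_all.append(vp)
        if s.t >= w0:
            in_window.append(vp)
    if len(in_window) < 2:
        raise ContractError(
            f"only {len(in_window)} samples inside the final {run.steady_window:g} min window"
        )
    return VpResult(
        vp_per_sample=vp_all,
        vp=float(np.mean(in_window)),
        window_used=run.steady_window,
        n_in_window=len(in_window),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# dye-dispersion flow rate
# ---------------------------------------------------------------------------

@dataclass
class DyeSeries:
    """Normalized dye-intensity time series (first image = 1)."""

    t: np.ndarray                # min
    intensity_norm: np.ndarray   # a.u.
    roi: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity_norm = np.asarray(self.intensity_norm, dtype=float)
        if len(self.t) != len(self.intensity_norm):
            raise ContractError("t and intensity_norm must have equal length")
        if len(self.t) and abs(self.t[0]) > 1e-12:
            raise ContractError("dye series must start at t = 0")
        if len(self.intensity_norm) and abs(self.intensity_norm[0] - 1.0) > 1e-9:
            raise ContractError("dye series must be normalized to the first image (=1)")


@dataclass
class DyeFlowResult:
    slope: float       # a.u./min
    intercept: float
    r2: float
    n: int
    window: tuple[float, float]


def dye_flow_rate(series: DyeSeries, window: tuple[float, float] = (0.0, 3.0)) -> DyeFlowResult:
    """OLS slope of normalized intensity vs time within ``window`` (min)."""
    sel = (series.t >= window[0] - 1e-12) & (series.t <= window[1] + 1e-12)
    if sel.sum() < 4:
        raise ContractError(f"need >= 4 points in window {window}, got {int(sel.sum())}")
    fit = stats.linregress(series.t[sel], series.intensity_norm[sel])
    return DyeFlowResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=int(sel.sum()),
        window=window,
    )


# ---------------------------------------------------------------------------
# brain water
# ---------------------------------------------------------------------------

@dataclass
class BrainWaterPair:
    wet: float   # g
    dry: float   # g

    def __post_init__(self) -> None:
        if not (0 < self.dry < self.wet):
            raise ContractError(f"need 0 < dry ({self.dry}) < wet ({self.wet})")


def brain_water_percent(pair: BrainWaterPair) -> float:
    """Brain water content as ``100 (wet − dry)/wet`` percent."""
    return 100.0 * (pair.wet - pair.dry) / pair.wet
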