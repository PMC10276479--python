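"""Seeded synthetic generators for every experimental input.

Each generator is a pure function of its spec plus a seed, and returns its
ground truth alongside the generated data, so every estimator in the
package can be validated by parameter recovery:

* :func:`gen_icp_trace` — ICP trace with cardiac, ventilation and drift
  components, Gaussian noise and Poisson-timed spikes;
* :func:`gen_infusion_study` / :func:`gen_step_trace` — constant-rate
  infusion plateaus governed by a true R_out;
* :func:`gen_perfusion_run` — dye-dilution samples governed by a true Vp
  (steady outflow ``Co = ri·Ci/(ri + Vp)``), optional equilibration ramp;
* :func:`gen_dye_series` — linear dye-dispersion intensity series;
* :func:`gen_efflux_series` / :func:`gen_efflux_fractions` —
  mono-exponential tracer release with counting noise, as paired
  control/bumetanide runs with full aliquot bookkeeping or as direct
  remaining-fraction series;
* :func:`gen_brain_water_pair`, :func:`gen_cohort` — wet/dry masses and
  whole cohorts parameterized from the bundled reference group table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._trace import PressureTrace
from .csf_dynamics import (
    BrainWaterPair,
    DyeSeries,
    InfusionStep,
    InfusionStudy,
    PerfusionRun,
    PerfusionSample,
)
from .errors import ContractError
from .tracer_flux import EffluxSeries

__all__ = [
    "TraceSpec",
    "TraceTruth",
    "CohortSpec",
    "GroupSpec",
    "reference_groups",
    "default_cohort_spec",
    "gen_icp_trace",
    "gen_step_trace",
    "gen_infusion_study",
    "gen_perfusion_run",
    "gen_dye_series",
    "gen_efflux_series",
    "gen_efflux_fractions",
    "gen_brain_water_pair",
    "gen_cohort",
]


def reference_groups() -> pd.DataFrame:
    """Bundled table of published group summaries (mean, SEM, n) per measure."""
    with resources.files("csfdyn.data").joinpath("reference_groups.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


# ---------------------------------------------------------------------------
# ICP traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Parameters of a synthetic ICP recording.

    Cardiac frequency should lie in the physiological 2.5–5 Hz heart-rate
    region; ventilation defaults to 1.3 Hz. ``pulse_shape`` may be
    ``"sine"`` or ``"asymmetric"`` (fundamental plus a second harmonic, to
    stress the peak-to-peak extractor).
    """

    duration: float = 300.0
    fs: float = 1000.0
    baseline: float = 3.4
    cardiac_freq: float = 4.0
    cardiac_p2p: float = 0.10
    ventilation_freq: float = 1.3
    ventilation_p2p: float = 0.6
    drift_period: float = 120.0
    drift_amplitude: float = 0.0
    noise_sd: float = 0.02
    spike_rate_per_min: float = 0.0
    spike_magnitude: float = 80.0
    pulse_shape: str = "sine"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cardiac_p2p, self.ventilation_p2p, self.drift_amplitude, self.noise_sd) < 0:
            raise ContractError("amplitudes and noise sd must be non-negative")
        if self.pulse_shape not in ("sine", "asymmetric"):
            raise ContractError(f"unknown pulse shape {self.pulse_shape!r}")


@dataclass
class TraceTruth:
    mwa: float                 # in-band peak-to-peak of the cardiac pulse
    baseline: float
    spike_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _cardiac_wave(theta: np.ndarray, shape: str, freq: float, band_hi: float = 5.5) -> np.ndarray:
    """Unit-peak-to-peak cardiac pulse train; harmonics above the analysis
    band are omitted from neither wave nor truth (truth is the p2p of the
    in-band content, computed by the caller)."""
    if shape == "sine":
        w = np.sin(theta)
    else:
        w = np.sin(theta) + 0.3 * np.sin(2 * theta + 0.5)
    return w


def gen_icp_trace(spec: TraceSpec) -> tuple[PressureTrace, TraceTruth]:
    """Synthetic ICP trace with known MWA, baseline and spike positions.

    The true MWA is the peak-to-peak amplitude of the cardiac pulse after
    restriction to harmonics inside the default 1.6–5.5 Hz band (for the
    sine shape this is simply ``cardiac_p2p``).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    theta = 2 * np.pi * spec.cardiac_freq * t

    wave = _cardiac_wave(theta, spec.pulse_shape, spec.cardiac_freq)
    # normalize the full pulse to unit p2p, then measure in-band p2p as truth
    dense = np.linspace(0, 2 * np.pi, 20001)
    full = _cardiac_wave(dense, spec.pulse_shape, spec.cardiac_freq)
    scale = 1.0 / np.ptp(full)
    wave = wave * scale * spec.cardiac_p2p
    if spec.pulse_shape == "sine" or 2 * spec.cardiac_freq <= 5.5:
        inband = full * scale
    else:
        inband = np.sin(dense) * scale
    true_mwa = float(np.ptp(inband)) * spec.cardiac_p2p

    p = (
        spec.baseline
        + wave
        + (spec.ventilation_p2p / 2) * np.sin(2 * np.pi * spec.ventilation_freq * t)
        + spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period)
        + rng.normal(0.0, spec.noise_sd, n)
    )
    spike_idx = np.empty(0, dtype=int)
    if spec.spike_rate_per_min > 0:
        n_spikes = rng.poisson(spec.spike_rate_per_min * spec.duration / 60.0)
        if n_spikes:
            spike_idx = np.sort(rng.choice(n, size=min(n_spikes, n), replace=False))
            p[spike_idx] += rng.choice([-1.0, 1.0], size=len(spike_idx)) * spec.spike_magnitude
    trace = PressureTrace(t=t, p=p, fs=spec.fs)
    return trace, TraceTruth(mwa=true_mwa, baseline=spec.baseline, spike_indices=spike_idx)


def gen_step_trace(
    start: float,
    plateau: float,
    duration: float,
    fs: float = 100.0,
    tau: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PressureTrace:
    """Exponential ramp-then-plateau pressure step (for plateau estimation)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    p = plateau + (start - plateau) * np.exp(-t / tau) + rng.normal(0.0, noise_sd, n)
    return PressureTrace(t=t, p=p, fs=fs)


# ---------------------------------------------------------------------------
# infusion / perfusion / dye / brain water
# ---------------------------------------------------------------------------

def gen_infusion_study(
    true_rout: float,
    icp_i: float = 3.4,
    rates: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    plateau_noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[InfusionStudy, float]:
    """Infusion study with plateaus ``icp_i + R_out·rate + noise``."""
    if true_rout < 0:
        raise ContractError("true R_out must be non-negative")
    rng = np.random.default_rng(seed)
    steps = [
        InfusionStep(rate=r, plateau=icp_i + true_rout * r + rng.normal(0.0, plateau_noise_sd))
        for r in rates
    ]
    return InfusionStudy(icp_i=icp_i, steps=steps), true_rout


def gen_perfusion_run(
    true_vp: float,
    ri: float = 9.0,
    ci: float = 1.0,
    cv: float = 0.05,
    n_samples: int = 12,
    dt_min: float = 5.0,
    equilibration_tau_min: float = 8.0,
    steady_window: float = 30.0,
    seed: int = 0,
) -> tuple[PerfusionRun, float]:
    """Perfusion run whose steady outflow obeys ``Co = ri·Ci/(ri + Vp)``.

    Early samples rise toward the steady level with time constant
    ``equilibration_tau_min`` (set to 0 for instant equilibration); each
    replicate carries multiplicative noise of the given CV.
    """
    if true_vp < 0:
        raise ContractError("true Vp must be non-negative")
    rng = np.random.default_rng(seed)
    co_ss = ri * ci / (ri + true_vp)

    def trip(mean: float) -> tuple[float, float, float]:
        return tuple(mean * (1.0 + rng.normal(0.0, cv, 3)))  # type: ignore[return-value]

    samples = []
    for i in range(n_samples):
        t = (i + 1) * dt_min
        if equilibration_tau_min > 0:
            co = co_ss * (1.0 - np.exp(-t / equilibration_tau_min))
        else:
            co = co_ss
        samples.append(PerfusionSample(t=t, co_triplicate=trip(co)))
    run = PerfusionRun(ci_triplicate=trip(ci), samples=samples, ri=ri, steady_window=steady_window)
    return run, true_vp


def gen_dye_series(
    slope: float,
    duration_min: float = 5.0,
    dt_min: float = 0.5,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[DyeSeries, float]:
    """Linear normalized dye-intensity series ``1 + slope·t`` with noise.

    The first point is exactly 1 (normalization to the first image)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    intensity = 1.0 + slope * t + rng.normal(0.0, noise_sd, len(t))
    intensity[0] = 1.0
    return DyeSeries(t=t, intensity_norm=intensity), slope


def gen_brain_water_pair(
    water_percent: float, wet_mass: float = 2.0, cv: float = 0.0, seed: int = 0
) -> tuple[BrainWaterPair, float]:
    """Wet/dry mass pair with the given true water percentage."""
    rng = np.random.default_rng(seed)
    wet = wet_mass * (1.0 + rng.normal(0.0, cv)) if cv > 0 else wet_mass
    dry = wet * (1.0 - water_percent / 100.0)
    return BrainWaterPair(wet=wet, dry=dry), water_percent


# ---------------------------------------------------------------------------
# efflux
# ---------------------------------------------------------------------------

def _one_efflux(
    rng: np.random.Generator,
    k: float,
    duration_min: float,
    dt_s: float,
    noise_cv: float,
    a0_cpm: float,
    aliquot_fraction: float,
    condition: str,
    pair_id: str,
) -> EffluxSeries:
    t = np.arange(dt_s, duration_min * 60.0 + dt_s / 2, dt_s)
    t_min = t / 60.0
    remaining = a0_cpm * np.exp(-k * t_min)
    edges = np.concatenate([[a0_cpm], remaining])
    released = -np.diff(edges)
    if noise_cv > 0:
        released = released * np.clip(1.0 + rng.normal(0.0, noise_cv, len(released)), 0.0, None)
    final = a0_cpm * np.exp(-k * duration_min)
    if noise_cv > 0:
        final *= max(1.0 + rng.normal(0.0, noise_cv), 1e-6)
    return EffluxSeries(
        t=t,
        aliquot_cpm=released * aliquot_fraction,
        final_tissue_cpm=final,
        aliquot_fraction=aliquot_fraction,
        condition=condition,
        pair_id=pair_id,
    )


def gen_efflux_series(
    k_total: float,
    k_insensitive: float,
    duration_min: float = 8.0,
    dt_s: float = 10.0,
    noise_cv: float = 0.0,
    a0_cpm: float = 2.0e4,
    aliquot_ul: float = 200.0,
    bath_ul: float = 1000.0,
    seed: int = 0,
    pair_id: str = "pair1",
) -> tuple[EffluxSeries, EffluxSeries, dict]:
    """Paired efflux runs: control decays at ``k_total``, the bumetanide run
    at ``k_insensitive``; the bumetanide-sensitive fraction is their
    difference. Aliquot/bath bookkeeping matches
    :func:`csfdyn.tracer_flux.reconstruct_remaining` exactly, so counts are
    conserved by construction.
    """
    if not (0 <= k_insensitive <= k_total):
        raise ContractError("need 0 <= k_insensitive <= k_total")
    rng = np.random.default_rng(seed)
    frac = aliquot_ul / bath_ul
    control = _one_efflux(rng, k_total, duration_min, dt_s, noise_cv, a0_cpm, frac, "control", pair_id)
    bum = _one_efflux(
        rng, k_insensitive, duration_min, dt_s, noise_cv, a0_cpm, frac, "bumetanide", pair_id
    )
    truth = {
        "k_total": k_total,
        "k_insensitive": k_insensitive,
        "k_sensitive": k_total - k_insensitive,
    }
    return control, bum, truth


def gen_efflux_fractions(
    k: float,
    duration_min: float = 8.0,
    dt_s: float = 10.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Remaining-fraction series ``e^{−kt}`` with i.i.d. multiplicative
    counting noise per time point (the measurement-noise model under which
    the log-linear fit's standard errors are calibrated)."""
    rng = np.random.default_rng(seed)
    t_min = np.arange(dt_s, duration_min * 60.0 + dt_s / 2, dt_s) / 60.0
    frac = np.exp(-k * t_min)
    if noise_cv > 0:
        frac = np.clip(frac * (1.0 + rng.normal(0.0, noise_cv, len(frac))), 1e-12, 1.0)
    return t_min, frac, k


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    mean: float
    sem: float
    n: int
    unit: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ContractError("group n must be >= 2")
        if self.sem < 0:
            raise ContractError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        """Per-animal SD reconstructed from the SEM: ``sem·sqrt(n)``."""
        return self.sem * np.sqrt(self.n)


@dataclass
class CohortSpec:
    """Per-measure, per-group sampling parameters. ``measures`` maps
    measure name → {group name → GroupSpec}."""

    measures: dict
    seed: int = 0
    heavy_tailed: bool = False


def default_cohort_spec(measures: list[str] | None = None, seed: int = 0) -> CohortSpec:
    """Cohort spec parameterized from the bundled reference group table."""
    ref = reference_groups()
    if measures is not None:
        ref = ref[ref["measure"].isin(measures)]
    spec: dict = {}
    for row in ref.itertuples():
        spec.setdefault(row.measure, {})[row.group] = GroupSpec(
            mean=float(row.mean), sem=float(row.sem), n=int(row.n), unit=str(row.unit)
        )
    return CohortSpec(measures=spec, seed=seed)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Cohort table with per-animal values drawn Normal(mean, sem·√n).

    With ``heavy_tailed`` the draws use a Student-t (df=3) scaled to the
    same SD, for stressing the Grubbs/normality stages. Returns the long
    table (animal_id, group, measure, value, unit) and the truth dict of
    group means.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: dict = {}
    for measure, groups in spec.measures.items():
        truth[measure] = {}
        for group, g in groups.items():
            truth[measure][group] = g.mean
            if spec.heavy_tailed:
                draws = g.mean + g.sd * rng.standard_t(3, g.n) / np.sqrt(3.0)
            else:
                draws = rng.normal(g.mean, g.sd, g.n)
            for i, v in enumerate(draws):
                rows.append(
                    {
                        "animal_id": f"{group}_{measure}_{i + 1:02d}",
                        "group": group,
                        "measure": measure,
                        "value": float(v),
                        "unit": g.unit,
                    }
                )
    return pd.DataFrame(rows), truth
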