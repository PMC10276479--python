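"""⁸⁶Rb⁺ influx/efflux kinetics with inhibitor-sensitive fractions.

Influx: tissue ⁸⁶Rb⁺ counts are corrected for extracellular background
using co-applied ³H-mannitol (an extracellular-space marker); the
ouabain-sensitive fraction of corrected uptake reflects Na⁺/K⁺-ATPase
activity.

Efflux: the remaining-activity series A_t/A_0 is reconstructed from timed
bath aliquots plus the dissolved end-point tissue (count-conserving
back-summation); the efflux rate constant k (min⁻¹) is −slope of the OLS
fit of ln(A_t/A_0) on time, and the bumetanide-sensitive fraction of k
reflects NKCC1 activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError

__all__ = [
    "InfluxMeasurement",
    "CorrectedInflux",
    "PairedDifference",
    "EffluxSeries",
    "RemainingActivity",
    "RateConstant",
    "correct_influx",
    "ouabain_sensitive",
    "reconstruct_remaining",
    "efflux_rate_constant",
    "bumetanide_sensitive",
]


# ---------------------------------------------------------------------------
# influx
# ---------------------------------------------------------------------------

@dataclass
class InfluxMeasurement:
    rb_cpm: float                    # tissue ⁸⁶Rb⁺ counts
    man_cpm: float                   # tissue ³H-mannitol counts
    medium_rb_cpm_per_ul: float
    medium_man_cpm_per_ul: float
    condition: str = "control"       # "control" | "ouabain"
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.rb_cpm < 0 or self.man_cpm < 0:
            raise ContractError("tissue counts must be non-negative")
        if self.medium_rb_cpm_per_ul <= 0 or self.medium_man_cpm_per_ul <= 0:
            raise ContractError("medium activities must be positive")


@dataclass
class CorrectedInflux:
    corrected_cpm: float
    v_ec_ul: float                   # apparent extracellular volume
    condition: str
    pair_id: str
    flagged: bool = False            # True when corrected uptake is negative


def correct_influx(m: InfluxMeasurement) -> CorrectedInflux:
    """Subtract the extracellular ⁸⁶Rb⁺ background estimated via mannitol.

    The mannitol space ``v_ec = man_cpm / medium_man_activity`` (µl) is
    assumed to hold medium-activity ⁸⁶Rb⁺; corrected uptake is
    ``rb_cpm − v_ec · medium_rb_activity``. Negative results are flagged.
    """
    v_ec = m.man_cpm / m.medium_man_cpm_per_ul
    corrected = m.rb_cpm - v_ec * m.medium_rb_cpm_per_ul
    return CorrectedInflux(
        corrected_cpm=float(corrected),
        v_ec_ul=float(v_ec),
        condition=m.condition,
        pair_id=m.pair_id,
        flagged=corrected < 0,
    )


@dataclass
class PairedDifference:
    value: float
    pair_id: str
    se: float | None = None
    flagged: bool = False


def ouabain_sensitive(control: CorrectedInflux, ouabain: CorrectedInflux) -> PairedDifference:
    """Ouabain-sensitive uptake (cpm): control − ouabain, paired."""
    if control.pair_id != ouabain.pair_id:
        raise ContractError(
            f"unpaired measurements: {control.pair_id!r} vs {ouabain.pair_id!r}"
        )
    if control.condition == ouabain.condition:
        raise ContractError("both measurements have the same condition")
    diff = control.corrected_cpm - ouabain.corrected_cpm
    return PairedDifference(value=float(diff), pair_id=control.pair_id, flagged=diff < 0)


# ---------------------------------------------------------------------------
# efflux
# ---------------------------------------------------------------------------

@dataclass
class EffluxSeries:
    """Timed bath-aliquot counts from one choroid plexus efflux run.

    ``aliquot_fraction`` is the sampled share of the bath at each time
    point (aliquot volume / bath volume); aliquot counts are scaled by its
    inverse to recover the counts released per interval.
    """

    t: np.ndarray                    # s, strictly increasing (10 s grid)
    aliquot_cpm: np.ndarray
    final_tissue_cpm: float
    aliquot_fraction: float
    condition: str = "control"       # "control" | "bumetanide"
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.aliquot_cpm = np.asarray(self.aliquot_cpm, dtype=float)
        if len(self.t) != len(self.aliquot_cpm):
            raise ContractError("t and aliquot_cpm must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ContractError("aliquot times must be strictly increasing")
        if self.final_tissue_cpm <= 0:
            raise ContractError("final tissue counts must be positive")
        if not (0 < self.aliquot_fraction <= 1):
            raise ContractError("aliquot fraction must be in (0, 1]")
        if np.any(self.aliquot_cpm < 0):
            raise ContractError("aliquot counts must be non-negative")


@dataclass
class RemainingActivity:
    """Remaining-activity fractions A_t/A_0 reconstructed from an efflux run."""

    t_min: np.ndarray
    remaining_frac: np.ndarray       # in (0, 1], non-increasing
    a0_cpm: float
    condition: str
    pair_id: str


def reconstruct_remaining(series: EffluxSeries) -> RemainingActivity:
    """Back-sum released counts to obtain A_t/A_0.

    Released counts per interval are ``aliquot_cpm / aliquot_fraction``;
    the initial activity is the dissolved end-point tissue plus everything
    released, so total counts are conserved exactly by construction.
    """
    released = series.aliquot_cpm / series.aliquot_fraction
    a0 = series.final_tissue_cpm + float(released.sum())
    remaining = a0 - np.cumsum(released)
    if np.any(remaining <= 0):
        raise ContractError("reconstructed remaining activity non-positive; counts inconsistent")
    return RemainingActivity(
        t_min=series.t / 60.0,
        remaining_frac=remaining / a0,
        a0_cpm=a0,
        condition=series.condition,
        pair_id=series.pair_id,
    )


@dataclass
class RateConstant:
    k: float                         # min⁻¹ (positive)
    se: float
    r2: float
    n_points: int
    condition: str = "control"
    pair_id: str = ""


def efflux_rate_constant(
    t_min: np.ndarray | RemainingActivity,
    remaining_frac: np.ndarray | None = None,
    condition: str = "control",
    pair_id: str = "",
) -> RateConstant:
    """Rate constant from the OLS fit of ln(A_t/A_0) on time (minutes).

    Accepts either a :class:`RemainingActivity` or explicit
    ``(t_min, remaining_frac)`` arrays. ``k = −slope`` is reported
    positive for decaying series, with the fit's standard error and r².
    """
    if isinstance(t_min, RemainingActivity):
        ra = t_min
        t, frac, condition, pair_id = ra.t_min, ra.remaining_frac, ra.condition, ra.pair_id
    else:
        t = np.asarray(t_min, dtype=float)
        frac = np.asarray(remaining_frac, dtype=float)
    if len(t) < 3:
        raise ContractError(f"need >= 3 points for the efflux fit, got {len(t)}")
    if np.any(frac <= 0) or np.any(frac > 1 + 1e-12):
        raise ContractError("remaining fractions must lie in (0, 1]")
    fit = stats.linregress(t, np.log(frac))
    return RateConstant(
        k=float(-fit.slope),
        se=float(fit.stderr),
        r2=float(fit.rvalue**2),
        n_points=len(t),
        condition=condition,
        pair_id=pair_id,
    )


def bumetanide_sensitive(k_control: RateConstant, k_bum: RateConstant) -> PairedDifference:
    """Bumetanide-sensitive efflux rate constant (min⁻¹), paired.

    The difference's standard error is propagated as
    ``sqrt(se_control² + se_bum²)``.
    """
    if k_control.pair_id != k_bum.pair_id:
        raise ContractError(
            f"unpaired rate constants: {k_control.pair_id!r} vs {k_bum.pair_id!r}"
        )
    if k_control.condition == k_bum.condition:
        raise ContractError("both rate constants have the same condition")
    diff = k_control.k - k_bum.k
    se = float(np.hypot(k_control.se, k_bum.se))
    return PairedDifference(value=float(diff), pair_id=k_control.pair_id, se=se, flagged=diff < 0)
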