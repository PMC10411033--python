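"""Uncertainty propagation, safety factors, tiers, and power limits.

Three uncorrelated relative uncertainties — modeling, intersubject variation,
and power monitoring — combine by root-sum-of-squares into a total relative
uncertainty; the safety factor is 1 plus that total.  Tier 2 assessments,
which validate only B1+ maps, multiply the safety factor by an additional
buffer (default 2).  The corrected peak SAR then sets the average-power
limit: total = SAR_limit / corrected_pSAR × reference_power, split equally
over channels.

Tier 1 needs no simulation at all: all RF power is assumed deposited in one
10-g averaging mass, giving a very conservative closed-form limit.

Two rounding modes are supported.  ``paper`` mirrors conventional report
arithmetic (safety factor and corrected pSAR rounded to one decimal before
the next step); ``full_precision`` carries doubles end to end.  Both are
recorded in every assessment.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

__all__ = [
    "UncertaintyBudget",
    "TierConfig",
    "TierAssessment",
    "combine_uncertainties",
    "safety_factor",
    "apply_buffer",
    "corrected_psar",
    "power_limit",
    "tier1_limit",
    "multiplicative_safety_factor",
    "run_tier_assessment",
]

DEFAULT_SAR_LIMIT = 20.0  # W/kg, first level controlled mode, head & trunk
DEFAULT_AVERAGING_MASS = 0.010  # kg (10 g)


@dataclasses.dataclass(frozen=True)
class UncertaintyBudget:
    """The three relative uncertainties of a pSAR estimate, as fractions.

    ``modeling_sources`` records which validation modalities produced the
    modeling term (e.g. ("B1",) or ("B1", "SAR")); tier 3 refuses a budget
    whose modeling uncertainty was derived from B1 mapping alone.
    """

    modeling: float
    intersubject: float
    power_monitoring: float
    provenance: Mapping[str, str] = dataclasses.field(default_factory=dict)
    modeling_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("modeling", "intersubject", "power_monitoring"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} uncertainty must be a finite fraction >= 0")
        object.__setattr__(self, "provenance", dict(self.provenance))
        object.__setattr__(
            self, "modeling_sources", tuple(str(s).upper() for s in self.modeling_sources)
        )

    @property
    def terms(self) -> tuple[float, float, float]:
        return (self.modeling, self.intersubject, self.power_monitoring)


@dataclasses.dataclass(frozen=True)
class TierConfig:
    """Configuration of a tier assessment.

    ``reference_power`` is the total input power (W) to which the simulated
    pSAR is normalized; ``psar_sim_mean`` is the mean simulated pSAR (W/kg)
    at that power, required for tiers 2–3 and meaningless for tier 1.
    """

    tier: int
    n_channels: int
    reference_power: float = 8.0
    psar_sim_mean: float | None = None
    buffer: float = 2.0
    sar_limit: float = DEFAULT_SAR_LIMIT
    averaging_mass: float = DEFAULT_AVERAGING_MASS
    rounding_mode: str = "paper"
    chain_efficiency: float = 1.0  # optional transmit-chain loss factor
    label: str = ""

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2, or 3")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for name in ("reference_power", "sar_limit", "averaging_mass", "chain_efficiency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.buffer < 1:
            raise ValueError("buffer must be >= 1")
        if self.rounding_mode not in ("paper", "full_precision"):
            raise ValueError("rounding_mode must be 'paper' or 'full_precision'")
        if self.tier in (2, 3) and self.psar_sim_mean is None:
            raise ValueError(f"tier {self.tier} requires psar_sim_mean")
        if self.tier == 1 and self.psar_sim_mean is not None:
            raise ValueError("tier 1 uses no simulation; psar_sim_mean must be absent")
        if self.psar_sim_mean is not None and self.psar_sim_mean <= 0:
            raise ValueError("psar_sim_mean must be > 0")


@dataclasses.dataclass(frozen=True)
class TierAssessment:
    """Full result of a tier assessment, with rounded and full-precision
    chains and an audit trail of inputs."""

    config: TierConfig
    budget: UncertaintyBudget | None
    total_relative_uncertainty: float | None
    safety_factor: float | None
    final_safety_factor: float | None
    corrected_psar: float | None
    total_power_limit: float
    per_channel_power_limit: float
    implied_tier1_sar: float | None
    full_precision: dict
    audit: dict

    def to_dict(self) -> dict:
        d = {
            "label": self.config.label,
            "tier": self.config.tier,
            "modeling": self.budget.modeling if self.budget else None,
            "intersubject": self.budget.intersubject if self.budget else None,
            "power_monitoring": self.budget.power_monitoring if self.budget else None,
            "total_relative_uncertainty": self.total_relative_uncertainty,
            "safety_factor": self.safety_factor,
            "buffer": self.config.buffer if self.config.tier == 2 else None,
            "final_safety_factor": self.final_safety_factor,
            "psar_sim_mean": self.config.psar_sim_mean,
            "corrected_psar": self.corrected_psar,
            "total_power_limit": self.total_power_limit,
            "per_channel_power_limit": self.per_channel_power_limit,
            "implied_tier1_sar": self.implied_tier1_sar,
            "full_precision": dict(self.full_precision),
            "audit": dict(self.audit),
        }
        return d


# ---------------------------------------------------------------------------
# Elementary operations


def combine_uncertainties(budget: UncertaintyBudget) -> float:
    """Root-sum-of-squares of the three relative uncertainties."""
    m, i, p = budget.terms
    return math.sqrt(m * m + i * i + p * p)


def safety_factor(total_uncertainty: float) -> float:
    """1 + total relative uncertainty."""
    if total_uncertainty < 0:
        raise ValueError("total uncertainty must be >= 0")
    return 1.0 + total_uncertainty


def apply_buffer(sf: float, tier: int, buffer: float) -> float:
    """Multiply the tier-2 safety factor by the buffer; tiers 1/3 unchanged."""
    if sf < 1:
        raise ValueError("safety factor must be >= 1")
    if buffer < 1:
        raise ValueError("buffer must be >= 1")
    if tier == 2:
        return sf * buffer
    return sf


def corrected_psar(psar_sim_mean: float, final_sf: float) -> float:
    """Simulated mean pSAR scaled by the final safety factor (W/kg)."""
    if psar_sim_mean <= 0 or final_sf <= 0:
        raise ValueError("inputs must be > 0")
    return psar_sim_mean * final_sf


def power_limit(
    corrected_psar_value: float,
    sar_limit: float,
    reference_power: float,
    n_channels: int,
) -> tuple[float, float]:
    """Average-power limit keeping corrected pSAR at the SAR limit.

    Returns (total W, per-channel W); power is split equally over channels.
    """
    if corrected_psar_value <= 0 or sar_limit <= 0 or reference_power <= 0:
        raise ValueError("inputs must be > 0")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    total = sar_limit / corrected_psar_value * reference_power
    return total, total / n_channels


def tier1_limit(
    sar_limit: float,
    n_channels: int,
    averaging_mass: float = DEFAULT_AVERAGING_MASS,
) -> tuple[float, float, float]:
    """Tier-1 closed form: all power dissipated in one averaging mass.

    Returns (total W, per-channel W, implied SAR in W/kg at 1 W/channel).
    """
    if sar_limit <= 0 or averaging_mass <= 0:
        raise ValueError("inputs must be > 0")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    total = sar_limit * averaging_mass
    implied = n_channels / averaging_mass  # SAR if every channel drives 1 W
    return total, total / n_channels, implied


def multiplicative_safety_factor(budget: UncertaintyBudget) -> float:
    """Conventional (over-conservative) propagation: Π(1 + term)."""
    sf = 1.0
    for term in budget.terms:
        sf *= 1.0 + term
    return sf


# ---------------------------------------------------------------------------
# Full chain


def _round1(x: float) -> float:
    # round-half-up at one decimal, matching hand arithmetic (2.75 -> 2.8)
    return math.floor(x * 10.0 + 0.5) / 10.0


def run_tier_assessment(
    config: TierConfig, budget: UncertaintyBudget | None = None
) -> TierAssessment:
    """Execute the full chain combine → safety factor → buffer → corrected
    pSAR → power limit, in both rounding modes.

    Tier 1 ignores the budget entirely.  Tiers 2–3 require all three budget
    terms; tier 3 additionally refuses a modeling uncertainty derived from
    B1 mapping alone (its ``modeling_sources`` must include SAR or TEMP
    validation when sources are declared).
    """
    audit: dict = {"rounding_mode": config.rounding_mode}

    if config.tier == 1:
        total, per_channel, implied = tier1_limit(
            config.sar_limit, config.n_channels, config.averaging_mass
        )
        full = {
            "total_power_limit": total,
            "per_channel_power_limit": per_channel,
            "implied_tier1_sar": implied,
        }
        audit["note"] = "tier 1: all power assumed dissipated in the averaging mass"
        return TierAssessment(
            config=config,
            budget=None,
            total_relative_uncertainty=None,
            safety_factor=None,
            final_safety_factor=None,
            corrected_psar=None,
            total_power_limit=total,
            per_channel_power_limit=per_channel,
            implied_tier1_sar=implied,
            full_precision=full,
            audit=audit,
        )

    if budget is None:
        raise ValueError(f"tier {config.tier} requires an uncertainty budget")
    if config.tier == 3 and budget.modeling_sources:
        if not ({"SAR", "TEMP"} & set(budget.modeling_sources)):
            raise ValueError(
                "tier 3 requires the modeling uncertainty to be validated by "
                "SAR/temperature mapping, not B1 mapping alone"
            )

    u = combine_uncertainties(budget)
    sf_exact = safety_factor(u)
    assert config.psar_sim_mean is not None
    ref_power = config.reference_power * config.chain_efficiency

    # full-precision chain
    fsf_exact = apply_buffer(sf_exact, config.tier, config.buffer)
    cp_exact = corrected_psar(config.psar_sim_mean, fsf_exact)
    tot_exact, per_exact = power_limit(
        cp_exact, config.sar_limit, ref_power, config.n_channels
    )
    full = {
        "total_relative_uncertainty": u,
        "safety_factor": sf_exact,
        "final_safety_factor": fsf_exact,
        "corrected_psar": cp_exact,
        "total_power_limit": tot_exact,
        "per_channel_power_limit": per_exact,
    }

    if config.rounding_mode == "paper":
        # safety factor and corrected pSAR are rounded to one decimal before
        # entering the next step, mirroring conventional report arithmetic
        sf = _round1(sf_exact)
        fsf = apply_buffer(sf, config.tier, config.buffer)
        cp = _round1(corrected_psar(config.psar_sim_mean, fsf))
        tot, per = power_limit(cp, config.sar_limit, ref_power, config.n_channels)
        audit["note"] = "safety factor and corrected pSAR rounded to 1 decimal"
    else:
        sf, fsf, cp, tot, per = sf_exact, fsf_exact, cp_exact, tot_exact, per_exact

    audit["inputs"] = {
        "budget": list(budget.terms),
        "modeling_sources": list(budget.modeling_sources),
        "provenance": dict(budget.provenance),
        "psar_sim_mean": config.psar_sim_mean,
        "reference_power": config.reference_power,
        "chain_efficiency": config.chain_efficiency,
        "sar_limit": config.sar_limit,
        "buffer": config.buffer if config.tier == 2 else None,
    }
    audit["multiplicative_safety_factor"] = multiplicative_safety_factor(budget)

    return TierAssessment(
        config=config,
        budget=budget,
        total_relative_uncertainty=u,
        safety_factor=sf,
        final_safety_factor=fsf,
        corrected_psar=cp,
        total_power_limit=tot,
        per_channel_power_limit=per,
        implied_tier1_sar=None,
        full_precision=full,
        audit=audit,
    )
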