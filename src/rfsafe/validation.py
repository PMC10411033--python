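"""Measurement-vs-simulation comparison and modeling uncertainty.

The modeling uncertainty of a simulated coil model is quantified voxel-wise:
the measured and simulated maps are subtracted, normalized by the in-mask
simulated maximum, and the positive error not exceeded in 99.9% of voxels
(nearest-rank quantile) is taken.  The worst case over all RF shims and
modalities becomes the final modeling uncertainty of the budget.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .core_maps import FieldMap, Modality

__all__ = [
    "ShimComparison",
    "ComparisonUncertainty",
    "ModelingUncertaintyResult",
    "diff_map_sar",
    "diff_map_b1",
    "modeling_uncertainty",
    "worst_case_uncertainty",
    "align_channel_phases",
]

DEFAULT_QUANTILE = 0.999


def _check_pair(meas: FieldMap, sim: FieldMap, modality: Modality) -> np.ndarray:
    for m, name in ((meas, "meas"), (sim, "sim")):
        if m.modality is not modality:
            raise ValueError(f"{name} must be a {modality.value} map, got {m.modality.value}")
    if meas.shape != sim.shape:
        raise ValueError(
            "grid mismatch between measurement and simulation; "
            "resample the simulation to the measurement grid first"
        )
    if (
        meas.norm_power is not None
        and sim.norm_power is not None
        and not math.isclose(meas.norm_power, sim.norm_power, rel_tol=1e-9)
    ):
        raise ValueError("maps are normalized to different input powers")
    mask = meas.mask & sim.mask
    if not mask.any():
        raise ValueError("measurement and simulation masks do not overlap")
    return mask


def diff_map_sar(meas: FieldMap, sim: FieldMap) -> np.ndarray:
    """Signed fractional difference (meas − sim) / max_in-mask(sim).

    Returns a grid with NaN outside the intersection mask.
    """
    mask = _check_pair(meas, sim, Modality.SAR)
    sim_max = float(np.max(sim.values[mask]))
    if sim_max <= 0:
        raise ValueError("simulated SAR maximum must be > 0")
    diff = np.full(meas.shape, np.nan)
    diff[mask] = (meas.values[mask] - sim.values[mask]) / sim_max
    return diff


def diff_map_b1(
    meas: FieldMap, sim: FieldMap, convention: str = "squared"
) -> np.ndarray:
    """Signed fractional B1+ difference map.

    ``squared`` (default): (|meas|² − |sim|²) / max(|sim|)² — the power-like
    convention matching SAR.  ``linear``: (meas − sim) / max(sim).
    """
    mask = _check_pair(meas, sim, Modality.B1)
    sim_max = float(np.max(sim.values[mask]))
    if sim_max <= 0:
        raise ValueError("simulated B1 maximum must be > 0")
    diff = np.full(meas.shape, np.nan)
    if convention == "squared":
        diff[mask] = (meas.values[mask] ** 2 - sim.values[mask] ** 2) / sim_max**2
    elif convention == "linear":
        diff[mask] = (meas.values[mask] - sim.values[mask]) / sim_max
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return diff


def nearest_rank_quantile(values: np.ndarray, quantile: float) -> float:
    """Nearest-rank empirical quantile: ascending sort, 1-based rank
    ceil(q·N).  No interpolation."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        raise ValueError("empty difference pool")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    rank = int(math.ceil(quantile * n))
    rank = min(max(rank, 1), n)
    return float(np.sort(values)[rank - 1])


def modeling_uncertainty(
    diffs: "np.ndarray | Sequence[np.ndarray]",
    quantile: float = DEFAULT_QUANTILE,
    clamp: bool = True,
) -> float:
    """The positive error not exceeded in ``quantile`` of all voxels.

    ``diffs`` is one signed-difference grid or a sequence to pool.  NaN
    (out-of-mask) entries are ignored.  A negative quantile — simulation
    systematically over-predicting measurement — is clamped to 0 by default;
    pass ``clamp=False`` for the raw signed value.
    """
    if isinstance(diffs, np.ndarray):
        pool = diffs.ravel()
    else:
        pool = np.concatenate([np.asarray(d, dtype=float).ravel() for d in diffs])
    q = nearest_rank_quantile(pool, quantile)
    if clamp:
        return max(q, 0.0)
    return q


@dataclasses.dataclass(frozen=True)
class ShimComparison:
    """Paired simulated/measured maps for one named RF shim and modality."""

    shim_name: str
    modality: Modality
    sim: FieldMap
    meas: FieldMap
    b1_convention: str = "squared"

    def diff(self) -> np.ndarray:
        if self.modality is Modality.SAR:
            return diff_map_sar(self.meas, self.sim)
        return diff_map_b1(self.meas, self.sim, convention=self.b1_convention)

    def uncertainty(self, quantile: float = DEFAULT_QUANTILE) -> "ComparisonUncertainty":
        diff = self.diff()
        raw = modeling_uncertainty(diff, quantile, clamp=False)
        n = int(np.isfinite(diff).sum())
        return ComparisonUncertainty(
            shim_name=self.shim_name,
            modality=self.modality,
            uncertainty=max(raw, 0.0),
            raw_quantile=raw,
            quantile=quantile,
            n_voxels=n,
        )


@dataclasses.dataclass(frozen=True)
class ComparisonUncertainty:
    """Per-shim, per-modality modeling uncertainty."""

    shim_name: str
    modality: Modality
    uncertainty: float
    raw_quantile: float
    quantile: float = DEFAULT_QUANTILE
    n_voxels: int = 0


@dataclasses.dataclass(frozen=True)
class ModelingUncertaintyResult:
    """Worst case over all per-comparison uncertainties, with provenance."""

    per_comparison: tuple[ComparisonUncertainty, ...]
    final: float
    worst: ComparisonUncertainty
    quantile: float


def worst_case_uncertainty(
    results: Iterable[ComparisonUncertainty],
    tier: int | None = None,
) -> ModelingUncertaintyResult:
    """Aggregate per-comparison uncertainties by taking the maximum.

    Tier 2 requires at least one B1 comparison; tier 3 additionally requires
    a SAR (temperature-derived) comparison, since B1 mapping alone cannot
    validate the quantity being limited.
    """
    results = tuple(results)
    if not results:
        raise ValueError("no comparison results to aggregate")
    modalities = {r.modality for r in results}
    if tier in (2, 3) and Modality.B1 not in modalities:
        raise ValueError(f"tier {tier} aggregation requires a B1 comparison")
    if tier == 3 and Modality.SAR not in modalities:
        raise ValueError(
            "tier 3 aggregation requires a SAR/temperature comparison in "
            "addition to B1 mapping"
        )
    worst = max(results, key=lambda r: r.uncertainty)
    return ModelingUncertaintyResult(
        per_comparison=results,
        final=worst.uncertainty,
        worst=worst,
        quantile=results[0].quantile,
    )


# ---------------------------------------------------------------------------
# Per-channel global phase alignment


def _phase_similarity(
    sim_phase: np.ndarray, meas_phase: np.ndarray, mask: np.ndarray
) -> float:
    """Masked mean structural similarity between two phase maps, computed on
    their (cos, sin) embedding so the score is insensitive to wrapping."""
    score = 0.0
    for comp in (np.cos, np.sin):
        a = np.where(mask, comp(sim_phase), 0.0)
        b = np.where(mask, comp(meas_phase), 0.0)
        _, smap = structural_similarity(
            a, b, data_range=2.0, full=True, gaussian_weights=False
        )
        score += float(np.mean(smap[mask]))
    return score / 2.0


def align_channel_phases(
    meas_phase_maps: Sequence[np.ndarray],
    sim_channel_fields: Sequence[np.ndarray],
    mask: np.ndarray | None = None,
    step_deg: float = 1.0,
) -> np.ndarray:
    """Recover per-channel global phase offsets between simulation and
    measurement.

    For each channel the constant offset in [0°, 360°) that maximizes the
    structural similarity between the simulated relative transmit-phase map
    (offset applied) and the measured one is found by grid search.

    Parameters
    ----------
    meas_phase_maps
        Per-channel measured relative phase grids, degrees.
    sim_channel_fields
        Per-channel simulated complex field grids (phases are taken from
        ``np.angle``) or real phase grids in degrees.
    """
    if len(meas_phase_maps) != len(sim_channel_fields):
        raise ValueError("channel count mismatch between measurement and simulation")
    offsets = np.empty(len(meas_phase_maps))
    candidates = np.arange(0.0, 360.0, step_deg)
    for c, (meas, sim) in enumerate(zip(meas_phase_maps, sim_channel_fields)):
        meas = np.asarray(meas)
        sim = np.asarray(sim)
        if np.iscomplexobj(sim):
            sim_phase = np.angle(sim)
        else:
            sim_phase = np.deg2rad(np.asarray(sim, dtype=float))
        meas_phase = np.deg2rad(np.asarray(meas, dtype=float))
        m = np.ones(meas_phase.shape, dtype=bool) if mask is None else mask
        best, best_score = 0.0, -np.inf
        for off in candidates:
            score = _phase_similarity(
                sim_phase + np.deg2rad(off), meas_phase, m
            )
            if score > best_score:
                best, best_score = off, score
        offsets[c] = best % 360.0
    return offsets
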