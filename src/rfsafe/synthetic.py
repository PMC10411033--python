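"""Seedable generators for multichannel phantom data.

The field model is a geometric surrogate, not an EM solution: each channel
sits on the phantom boundary and contributes a complex field whose magnitude
decays exponentially with distance from the channel and whose phase advances
linearly with that distance.  This reproduces the statistical structure the
pipeline assumes (smooth per-channel fields, coherent shim combination,
constructive/destructive interference) without any solver.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_maps import FieldMap, Modality, TemperatureSeries

__all__ = [
    "ChannelFields",
    "synth_channel_fields",
    "combine_shim",
    "perturb_measurement",
    "synth_temperature_series",
    "synth_psar_population",
    "NAMED_SHIMS",
]

# canonical 8-channel phase vocabularies used throughout the tests
NAMED_SHIMS: dict[str, "tuple[float, ...]"] = {
    "zero_phase": tuple([0.0] * 8),
    "alternating_0_180": tuple([0.0, 180.0] * 4),
    "left": tuple(np.linspace(0.0, 315.0, 8)),
    "right": tuple(np.linspace(315.0, 0.0, 8)),
}


@dataclasses.dataclass(frozen=True)
class ChannelFields:
    """Per-channel complex B1 surrogates and E-field surrogates on a grid."""

    b1: np.ndarray  # (n_channels, *shape) complex
    e_basis: np.ndarray  # (n_channels, *shape) complex, SAR ∝ |Σ drive·e|²
    mask: np.ndarray  # phantom mask
    spacing: tuple[float, ...]
    metadata: dict

    @property
    def n_channels(self) -> int:
        return self.b1.shape[0]


def synth_channel_fields(
    shape: Sequence[int] = (64, 64),
    spacing: Sequence[float] = (4.0, 4.0),
    n_channels: int = 8,
    phantom_radius: float = 0.8,
    decay_length: float = 0.35,
    seed: int = 0,
    angle_jitter: float = 0.02,
) -> ChannelFields:
    """Generate per-channel complex field surrogates on an elliptical phantom.

    ``phantom_radius`` and ``decay_length`` are fractions of the half-extent
    of the grid.  Channels are placed at equal angles on the phantom
    boundary.  The channel field magnitude decays as exp(-d/decay) with
    distance d from the channel and its phase advances linearly in d, so
    symmetric antiphase drives interfere destructively on the midline.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 2:
        raise ValueError("synthetic fields are generated on 2D grids")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0 < phantom_radius <= 1.0:
        raise ValueError("phantom must fit inside the grid (0 < radius <= 1)")
    rng = np.random.default_rng(seed)

    ny, nx = shape
    y, x = np.meshgrid(
        np.linspace(-1.0, 1.0, ny), np.linspace(-1.0, 1.0, nx), indexing="ij"
    )
    # slightly elliptical phantom
    ell = np.sqrt((x / phantom_radius) ** 2 + (y / (0.85 * phantom_radius)) ** 2)
    mask = ell <= 1.0

    angles = 2.0 * np.pi * np.arange(n_channels) / n_channels
    # small seeded jitter so channels are not perfectly symmetric
    if angle_jitter > 0:
        angles = angles + rng.uniform(-angle_jitter, angle_jitter, size=n_channels)

    k_phase = np.pi / max(decay_length, 1e-6) * 0.25  # phase advance per unit d
    b1 = np.empty((n_channels,) + shape, dtype=complex)
    e = np.empty_like(b1)
    for c, a in enumerate(angles):
        cx = phantom_radius * np.cos(a)
        cy = 0.85 * phantom_radius * np.sin(a)
        d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        mag = np.exp(-d / decay_length)
        field = mag * np.exp(1j * k_phase * d)
        # E surrogate: steeper decay near the channel, same phase structure
        emag = np.exp(-d / (0.6 * decay_length))
        b1[c] = np.where(mask, field, 0.0)
        e[c] = np.where(mask, emag * np.exp(1j * k_phase * d), 0.0)

    return ChannelFields(
        b1=b1,
        e_basis=e,
        mask=mask,
        spacing=tuple(float(s) for s in spacing),
        metadata={
            "n_channels": n_channels,
            "phantom_radius": phantom_radius,
            "decay_length": decay_length,
            "seed": seed,
            "phantom": {"eps_r": 37.0, "sigma_S_per_m": 0.4},
        },
    )


def combine_shim(
    fields: ChannelFields,
    phases_deg: Sequence[float],
    powers_w: Sequence[float],
    b1_scale: float = 1.0,
    sar_scale: float = 1.0,
) -> tuple[FieldMap, FieldMap]:
    """Coherently combine channel fields under an RF shim.

    Each channel is driven with weight sqrt(power)·exp(i·phase); the B1 map
    is the magnitude of the complex sum (μT surrogate) and the SAR map the
    squared magnitude of the E-surrogate sum (W/kg surrogate).  The returned
    maps are normalized to ``norm_power = Σ powers``.
    """
    phases = np.asarray(phases_deg, dtype=float)
    powers = np.asarray(powers_w, dtype=float)
    if phases.size != fields.n_channels or powers.size != fields.n_channels:
        raise ValueError("phases and powers must match the channel count")
    if np.any(powers < 0):
        raise ValueError("powers must be >= 0")
    drive = np.sqrt(powers) * np.exp(1j * np.deg2rad(phases))
    b1_sum = np.tensordot(drive, fields.b1, axes=(0, 0))
    e_sum = np.tensordot(drive, fields.e_basis, axes=(0, 0))
    total_power = float(powers.sum())
    norm = total_power if total_power > 0 else None
    b1_map = FieldMap(
        values=np.abs(b1_sum) * b1_scale,
        spacing=fields.spacing,
        modality=Modality.B1,
        mask=fields.mask,
        norm_power=norm,
    )
    sar_map = FieldMap(
        values=np.abs(e_sum) ** 2 * sar_scale,
        spacing=fields.spacing,
        modality=Modality.SAR,
        mask=fields.mask,
        norm_power=norm,
    )
    return b1_map, sar_map


def _correlated_field(
    shape: tuple[int, ...], corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length
    in voxels (white noise + Gaussian smoothing)."""
    white = rng.standard_normal(shape)
    if corr_length > 0:
        field = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
        sd = field.std()
        if sd > 0:
            field = field / sd
    else:
        field = white
    return field


def perturb_measurement(
    fmap: FieldMap,
    scale_error: float = 0.0,
    corr_noise_sigma: float = 0.0,
    corr_length: float = 0.0,
    seed: int = 0,
) -> FieldMap:
    """Emulate a measured map: scale the truth and add smooth correlated noise.

    meas = map · (1 + scale_error) + noise, where the noise field has the
    given correlation length (voxels) and standard deviation
    ``corr_noise_sigma`` relative to the in-mask maximum.  The mask is
    preserved; B1/SAR outputs are floored at 0 to stay physical.
    """
    if corr_noise_sigma < 0 or corr_length < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    values = fmap.values * (1.0 + scale_error)
    if corr_noise_sigma > 0:
        noise = _correlated_field(fmap.shape, corr_length, rng)
        values = values + corr_noise_sigma * fmap.in_mask_max() * noise
    if fmap.modality in (Modality.B1, Modality.SAR):
        values = np.clip(values, 0.0, None)
    values = np.where(fmap.mask, values, np.nan)
    return fmap.replace(values=values, mask=fmap.mask.copy())


def synth_temperature_series(
    sar_map: FieldMap,
    Cp: float = 4000.0,
    duration_s: float = 60.0,
    frame_interval_s: float = 5.0,
    noise_sigma_K: float = 0.0,
    seed: int = 0,
    T0: float = 20.0,
    saturation_tau_s: float | None = None,
) -> TemperatureSeries:
    """Linear-plus-noise heating curves driven by a SAR map.

    T(x, t) = T0 + (SAR(x)/Cp)·t + N(0, σ) per frame; with
    ``saturation_tau_s`` set, the linear ramp is replaced by the saturating
    curve τ·(1 − exp(−t/τ))·SAR/Cp (off by default).
    """
    if duration_s <= 0 or frame_interval_s <= 0 or Cp <= 0:
        raise ValueError("duration, frame interval, and Cp must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 0.5 * frame_interval_s, frame_interval_s)
    rate = np.where(sar_map.mask, sar_map.values / Cp, 0.0)
    frames = []
    for t in times:
        if saturation_tau_s is not None:
            ramp = saturation_tau_s * (1.0 - np.exp(-t / saturation_tau_s))
        else:
            ramp = t
        T = T0 + rate * ramp
        if noise_sigma_K > 0:
            T = T + rng.normal(0.0, noise_sigma_K, size=T.shape)
        frames.append(
            FieldMap(
                values=np.where(sar_map.mask, T, np.nan),
                spacing=sar_map.spacing,
                modality=Modality.TEMP,
                mask=sar_map.mask,
            )
        )
    return TemperatureSeries(frames=tuple(frames), times=tuple(times), Cp=Cp)


def synth_psar_population(
    gamma_shape: float, gamma_scale: float, n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. gamma-distributed pSAR draws (W/kg), deterministic per seed."""
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma parameters must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(gamma_shape, gamma_scale, size=n)
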