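"""Field-map data model, I/O, and grid preprocessing.

A :class:`FieldMap` holds scalar values (B1+ magnitude in μT, SAR in W/kg, or
temperature in °C/K) on a regular 2D/3D voxel grid together with per-axis
spacing, an in-phantom mask, and the total input power the map is normalized
to.  All downstream statistics operate only on in-mask voxels.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "FieldMap",
    "TemperatureSeries",
    "read_field_map",
    "write_field_map",
    "resample_to_grid",
    "erode_mask",
    "gaussian_smooth",
    "gaussian_kernel",
]


class Modality(str, enum.Enum):
    """Physical quantity stored in a map."""

    B1 = "B1"
    SAR = "SAR"
    TEMP = "TEMP"


def _as_modality(modality: "Modality | str") -> Modality:
    if isinstance(modality, Modality):
        return modality
    return Modality(str(modality).upper())


@dataclasses.dataclass(frozen=True)
class FieldMap:
    """Scalar values on a regular voxel grid.

    Parameters
    ----------
    values
        2D or 3D float array.
    spacing
        Per-axis voxel size in mm, one entry per array axis, all > 0.
    mask
        Boolean array, same shape as ``values``; True = inside phantom.
        Defaults to all finite voxels.
    modality
        One of ``B1`` (μT), ``SAR`` (W/kg), ``TEMP`` (°C or K).
    norm_power
        Total input power in W the map is normalized to.  Not meaningful
        for TEMP maps.
    """

    values: np.ndarray
    spacing: tuple[float, ...]
    modality: Modality
    mask: np.ndarray = None  # type: ignore[assignment]
    norm_power: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim not in (2, 3):
            raise ValueError(f"values must be 2D or 3D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "modality", _as_modality(self.modality))

        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(spacing) == 1:
            spacing = spacing * values.ndim
        if len(spacing) != values.ndim:
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing entries must be > 0")
        object.__setattr__(self, "spacing", spacing)

        if self.mask is None:
            mask = np.isfinite(values)
        else:
            mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask and values must have identical shape")
        mask = mask & np.isfinite(values)
        object.__setattr__(self, "mask", mask)

        if self.modality in (Modality.SAR, Modality.B1) and mask.any():
            if np.any(values[mask] < 0):
                raise ValueError(
                    f"{self.modality.value} maps must be non-negative inside the mask"
                )
        if self.norm_power is not None and self.norm_power <= 0:
            raise ValueError("norm_power must be > 0")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def in_mask(self) -> np.ndarray:
        """Flat array of the in-mask values."""
        return self.values[self.mask]

    def in_mask_max(self) -> float:
        """Maximum in-mask value; must be finite and > 0 when the map is a
        normalization reference."""
        vals = self.in_mask()
        if vals.size == 0:
            raise ValueError("map has no in-mask voxels")
        return float(np.max(vals))

    def replace(self, **kwargs) -> "FieldMap":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class TemperatureSeries:
    """Ordered temperature frames with acquisition times and heat capacity.

    ``Cp`` is the specific heat capacity of the phantom in J/(kg·K); the
    voxel-wise heating slope dT/dt multiplied by Cp gives SAR in W/kg.
    """

    frames: tuple[FieldMap, ...]
    times: tuple[float, ...]
    Cp: float

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        times = tuple(float(t) for t in self.times)
        if len(frames) != len(times):
            raise ValueError("frames and times must have equal length")
        if len(frames) < 2:
            raise ValueError("a temperature series needs at least 2 frames")
        if times[0] < 0:
            raise ValueError("times must start at >= 0 s")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        ref = frames[0]
        for f in frames:
            if f.modality is not Modality.TEMP:
                raise ValueError("all frames must be TEMP maps")
            if f.shape != ref.shape or f.spacing != ref.spacing:
                raise ValueError("all frames must share shape and spacing")
        if self.Cp <= 0:
            raise ValueError("Cp must be > 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    @property
    def mask(self) -> np.ndarray:
        """Intersection mask over all frames."""
        m = self.frames[0].mask.copy()
        for f in self.frames[1:]:
            m &= f.mask
        return m

    def stack(self) -> np.ndarray:
        """Frames stacked along a leading time axis."""
        return np.stack([f.values for f in self.frames], axis=0)


# ---------------------------------------------------------------------------
# I/O


def _read_tsv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path} contains no data")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path} is not a rectangular matrix")
    return np.array(rows, dtype=float)


def read_field_map(
    path: "str | Path",
    format: str | None = None,
    *,
    modality: "Modality | str",
    spacing: "Sequence[float] | float" = 1.0,
    norm_power: float | None = None,
) -> FieldMap:
    """Read a field map from NIfTI or a delimited-text matrix.

    NaN voxels are masked out; they never enter downstream statistics.
    Negative values in a SAR or B1 map raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "nifti" if ".nii" in path.suffixes or path.suffix in (".nii", ".gz") else "tsv"
    if format == "nifti":
        img = nib.load(str(path))
        values = np.asarray(img.get_fdata(), dtype=float)
        values = np.squeeze(values)
        zooms = img.header.get_zooms()[: values.ndim]
        spacing = tuple(float(z) for z in zooms)
    elif format == "tsv":
        values = _read_tsv_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return FieldMap(
        values=values,
        spacing=spacing,
        modality=modality,
        norm_power=norm_power,
    )


def write_field_map(fmap: FieldMap, path: "str | Path", format: str | None = None) -> Path:
    """Write a map to NIfTI or text; out-of-mask voxels are stored as NaN."""
    path = Path(path)
    if format is None:
        format = "nifti" if ".nii" in path.suffixes else "tsv"
    values = fmap.values.copy()
    values[~fmap.mask] = np.nan
    if format == "nifti":
        affine = np.diag(list(fmap.spacing) + [1.0] * (4 - fmap.ndim))
        img = nib.Nifti1Image(values, affine)
        img.header.set_zooms(fmap.spacing)
        nib.save(img, str(path))
    elif format == "tsv":
        if fmap.ndim != 2:
            raise ValueError("tsv format stores 2D slices only")
        np.savetxt(path, values, delimiter="\t", fmt="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Grid preprocessing


def resample_to_grid(
    fmap: FieldMap,
    target_shape: Sequence[int],
    method: str = "block_average",
) -> FieldMap:
    """Downsample a map onto a coarser grid covering the same extent.

    Only downsampling is supported: simulations are resampled at the lower
    resolution of the measurements, never the reverse.  ``block_average``
    requires each axis to divide evenly and averages non-overlapping blocks;
    the output mask keeps a voxel only when *all* contributing source voxels
    are in-mask.  ``linear`` interpolates at the target voxel centers.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != fmap.ndim:
        raise ValueError("target shape rank must match the map")
    if any(t > s for t, s in zip(target_shape, fmap.shape)):
        raise ValueError(
            "upsampling requested; only resampling to a coarser grid is supported"
        )
    factors = tuple(s / t for s, t in zip(fmap.shape, target_shape))
    new_spacing = tuple(sp * f for sp, f in zip(fmap.spacing, factors))

    if method == "block_average":
        if any(s % t != 0 for s, t in zip(fmap.shape, target_shape)):
            raise ValueError(
                "block_average requires integer downsampling factors; use method='linear'"
            )
        ifactors = tuple(int(f) for f in factors)
        vals = fmap.values.copy()
        vals[~fmap.mask] = 0.0
        # reshape to (t0, f0, t1, f1, ...) and reduce the factor axes
        newshape: list[int] = []
        for t, f in zip(target_shape, ifactors):
            newshape.extend([t, f])
        blocks = vals.reshape(newshape)
        maskblocks = fmap.mask.reshape(newshape)
        reduce_axes = tuple(range(1, 2 * fmap.ndim, 2))
        count = maskblocks.sum(axis=reduce_axes)
        total = blocks.sum(axis=reduce_axes)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        newmask = maskblocks.all(axis=reduce_axes)
    elif method == "linear":
        coords = np.meshgrid(
            *[
                (np.arange(t) + 0.5) * f - 0.5
                for t, f in zip(target_shape, factors)
            ],
            indexing="ij",
        )
        coords = np.stack(coords, axis=0)
        vals = fmap.values.copy()
        vals[~fmap.mask] = 0.0
        out = ndimage.map_coordinates(vals, coords, order=1, mode="nearest")
        maskf = ndimage.map_coordinates(
            fmap.mask.astype(float), coords, order=1, mode="nearest"
        )
        newmask = maskf > 0.999  # all contributing voxels in-mask
        out = np.where(newmask, out, np.nan)
    else:
        raise ValueError(f"unknown resampling method {method!r}")

    return FieldMap(
        values=out,
        spacing=new_spacing,
        modality=fmap.modality,
        mask=newmask,
        norm_power=fmap.norm_power,
    )


def erode_mask(mask: np.ndarray, depth: int) -> np.ndarray:
    """Erode a boolean mask by ``depth`` voxels in Chebyshev distance.

    Voxels beyond the grid border count as outside, so a full-grid mask
    loses its ``depth`` outermost layers.  ``depth=0`` returns a copy.
    """
    mask = np.asarray(mask, dtype=bool)
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return mask.copy()
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    return ndimage.binary_erosion(
        mask, structure=structure, iterations=depth, border_value=0
    )


def gaussian_kernel(size: int = 3, sigma: float = 0.8, ndim: int = 2) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel of odd ``size`` per axis."""
    if size % 2 != 1 or size < 1:
        raise ValueError("kernel size must be a positive odd integer")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    kernel = g1
    for _ in range(ndim - 1):
        kernel = np.multiply.outer(kernel, g1)
    return kernel / kernel.sum()


def gaussian_smooth(
    fmap: FieldMap, kernel_size: int = 3, sigma: float = 0.8
) -> FieldMap:
    """Mask-aware Gaussian smoothing (normalized convolution), per 2D slice.

    Out-of-mask voxels never contribute; the kernel weights are renormalized
    over the in-mask neighborhood, so constants map to constants and the
    output stays within the input's in-mask [min, max].
    """
    plane = fmap.shape[-2:]
    if kernel_size > min(plane):
        raise ValueError("kernel larger than map")
    kernel = gaussian_kernel(kernel_size, sigma, ndim=2)

    def smooth2d(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
        v = np.where(mask, vals, 0.0)
        num = ndimage.convolve(v, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(mask & (den > 0), num / den, np.nan)
        return out

    if fmap.ndim == 2:
        out = smooth2d(fmap.values, fmap.mask)
    else:
        out = np.empty_like(fmap.values)
        for k in range(fmap.shape[0]):
            out[k] = smooth2d(fmap.values[k], fmap.mask[k])
    return fmap.replace(values=out, mask=fmap.mask.copy())
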