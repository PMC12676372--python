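"""Shared data model: masking, gather/scatter, bound transforms, validation.

Conventions used throughout the package:

* arrays are 0-based with spatial dimensions first ("volume" layout:
  first 3 dims spatial, trailing dims measurement) or a flat sample axis
  first ("list" layout);
* the gather/scatter flat ordering is the **column-major (Fortran)
  linear index over the spatial dims**, fixed so flat layouts are
  reproducible across runs;
* parameter bounds are enforced with a scaled-logit transform
  ``theta = lb + (ub - lb) * sigmoid(z)``, which is differentiable and
  maps the whole real line strictly into ``(lb, ub)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "AcquisitionGrid",
    "BoundSpec",
    "ParameterMaps",
    "ValidationError",
    "from_unconstrained",
    "gather",
    "mask_flat_indices",
    "scatter",
    "to_unconstrained",
    "validate_inputs",
]


class ValidationError(ValueError):
    """Raised when inputs violate the data-model contracts."""


@dataclass
class AcquisitionGrid:
    """Named acquisition-parameter arrays (echo times in ms, b-values, ...).

    Arrays must be finite and broadcastable against the measurement
    dimensions of the signal they describe.
    """

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, arr in self.arrays.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"acquisition array {name!r} contains non-finite values")
            clean[name] = arr
        self.arrays = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def __contains__(self, name: str) -> bool:
        return name in self.arrays


class BoundSpec(dict):
    """Per-parameter ``(lower, upper)`` box bounds, both finite, lb < ub."""

    def __init__(self, bounds: dict[str, tuple[float, float]]):
        super().__init__()
        for name, (lb, ub) in bounds.items():
            lb, ub = float(lb), float(ub)
            if not (np.isfinite(lb) and np.isfinite(ub)):
                raise ValidationError(f"bounds for {name!r} must be finite")
            if not lb < ub:
                raise ValidationError(f"bounds for {name!r} need lower < upper, got ({lb}, {ub})")
            self[name] = (lb, ub)

    def midpoint(self) -> dict[str, float]:
        return {k: 0.5 * (lb + ub) for k, (lb, ub) in self.items()}


@dataclass
class ParameterMaps:
    """Named parameter arrays sharing one spatial (or flat) shape."""

    maps: dict[str, np.ndarray]
    bounds: BoundSpec | None = None

    def __post_init__(self):
        shapes = {k: np.asarray(v).shape for k, v in self.maps.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"parameter arrays have inconsistent shapes: {shapes}")
        self.maps = {k: np.asarray(v, dtype=float) for k, v in self.maps.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def shape(self):
        return next(iter(self.maps.values())).shape


# -- gather / scatter ----------------------------------------------------------

def mask_flat_indices(mask: np.ndarray) -> np.ndarray:
    """C-order flat spatial indices of True voxels, sorted in Fortran order.

    This fixes the documented gather ordering: voxels are enumerated by
    the column-major linear index over the spatial dims.
    """
    mask = np.asarray(mask, dtype=bool)
    f_ids = np.flatnonzero(mask.ravel(order="F"))
    multi = np.unravel_index(f_ids, mask.shape, order="F")
    return np.ravel_multi_index(multi, mask.shape, order="C")


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask has no True voxels")
    return mask


def gather(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Volume layout -> list layout: (n_masked, *trailing) in Fortran order."""
    mask = _check_mask(mask)
    volume = np.asarray(volume)
    nd = mask.ndim
    if volume.shape[:nd] != mask.shape:
        raise ValidationError(
            f"volume spatial shape {volume.shape[:nd]} does not match mask shape {mask.shape}"
        )
    flat = volume.reshape(mask.size, *volume.shape[nd:])
    return flat[mask_flat_indices(mask)]


def scatter(flat: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """List layout -> volume layout, inverse of :func:`gather`."""
    mask = _check_mask(mask)
    flat = np.asarray(flat)
    n = int(mask.sum())
    if flat.shape[0] != n:
        raise ValidationError(f"flat has {flat.shape[0]} rows but mask has {n} True voxels")
    out = np.full((mask.size, *flat.shape[1:]), fill, dtype=flat.dtype)
    out[mask_flat_indices(mask)] = flat
    return out.reshape(*mask.shape, *flat.shape[1:])


# -- bound transforms ----------------------------------------------------------

_CLAMP_EPS = 1e-9  # relative clamp distance from a bound


def to_unconstrained(theta: dict[str, np.ndarray], bounds: BoundSpec) -> dict[str, np.ndarray]:
    """Scaled-logit forward transform; clamps boundary values with a warning."""
    out = {}
    for name, arr in theta.items():
        lb, ub = bounds[name]
        arr = np.asarray(arr, dtype=float)
        eps = _CLAMP_EPS * (ub - lb)
        if np.any(arr <= lb) or np.any(arr >= ub):
            warnings.warn(
                f"parameter {name!r} touches its bounds; clamping inside ({lb}, {ub})",
                stacklevel=2,
            )
            arr = np.clip(arr, lb + eps, ub - eps)
        u = (arr - lb) / (ub - lb)
        out[name] = np.log(u) - np.log1p(-u)
    return out


def from_unconstrained(z: dict[str, object], bounds: BoundSpec) -> dict[str, object]:
    """Inverse transform; works on ndarrays and autodiff Tensors alike.

    Parameters absent from ``bounds`` pass through unchanged (identity
    parametrisation, used by the unbounded reconstruction unknowns).
    """
    out = {}
    for name, arr in z.items():
        if bounds is None or name not in bounds:
            out[name] = arr
            continue
        lb, ub = bounds[name]
        out[name] = lb + (ub - lb) * ad.sigmoid(arr)
    return out


# -- validation ----------------------------------------------------------------

@dataclass
class ValidatedBundle:
    signal: np.ndarray
    mask: np.ndarray
    weights: np.ndarray
    grid: AcquisitionGrid
    layout: str  # "volume" or "list"
    spatial_ndim: int


def validate_inputs(signal, mask=None, weights=None, grid=None, layout="volume") -> ValidatedBundle:
    """Check shapes/NaNs and normalise the optional inputs.

    Values inside the mask are never mutated; NaNs outside the mask are
    accepted (they never enter the loss).
    """
    signal = np.asarray(signal)
    if layout not in ("volume", "list"):
        raise ValidationError(f"unknown layout {layout!r}")
    spatial_ndim = 3 if layout == "volume" else 1
    if signal.ndim < spatial_ndim + 1:
        raise ValidationError("signal needs at least one measurement dimension")
    spatial_shape = signal.shape[:spatial_ndim]

    if mask is None:
        mask = np.ones(spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial_shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match signal spatial shape {spatial_shape}"
        )
    if not mask.any():
        raise ValidationError("mask has no True voxels")

    inside = signal[mask]
    if np.any(np.isnan(inside)):
        raise ValidationError("signal contains NaN inside the mask")

    if weights is None:
        weights = np.ones_like(signal, dtype=float)
    else:
        weights = np.asarray(weights, dtype=float)
        try:
            weights = np.broadcast_to(weights, signal.shape).copy()
        except ValueError as e:
            raise ValidationError(f"weights not broadcastable to signal shape: {e}") from None
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")

    if grid is None:
        grid = AcquisitionGrid({})
    elif isinstance(grid, dict):
        grid = AcquisitionGrid(grid)

    return ValidatedBundle(signal, mask, weights, grid, layout, spatial_ndim)
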