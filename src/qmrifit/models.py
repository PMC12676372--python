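"""Forward signal models and the pluggable model contract.

A :class:`ForwardModel` maps named parameter arrays plus an acquisition
grid to a predicted-signal array shaped exactly like the measured data.
The same model object serves both solvers: the gradient solver evaluates
it on autodiff Tensors, the MCMC sampler on plain ndarrays — model code
is written once against :mod:`qmrifit.autodiff`'s dispatching functions.

Built-ins:

* ``monoexp_r2s`` — single-compartment R2* relaxometry,
  ``S(t) = S0 * exp(-t * R2star)``;
* ``twopool_gre`` — a two-pool GRE decay,
  ``S(t) = S0 * (f * exp(-t*R2a) + (1-f) * exp(-t*R2b))``, an
  ill-conditioned demo model motivating regularisation;
* ``gaussian_mean`` — identity model for sampler validation;
* ``sense`` — the SENSE/CAIPI encoding operator (image -> multi-coil
  undersampled k-space) used by the reconstruction application.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .core import AcquisitionGrid, BoundSpec, ValidationError

__all__ = [
    "ForwardModel",
    "GaussianMeanModel",
    "MonoExpR2s",
    "SenseModel",
    "TwoPoolGre",
    "get_model",
    "list_models",
    "monoexp_signal",
    "register_model",
    "sense_adjoint",
    "sense_forward",
    "twopool_signal",
]


# -- closed-form signal kernels ------------------------------------------------

def monoexp_signal(S0, R2star, t):
    """Mono-exponential GRE decay ``S0 * exp(-t * R2star)``.

    ``t`` (echo times, ms) broadcasts along a new trailing axis; ``S0``
    and ``R2star`` may have any common leading shape (voxels).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("echo times must be nonnegative")
    S0e = ad.expand_dims(S0, -1) if not np.isscalar(S0) else S0
    R2e = ad.expand_dims(R2star, -1) if not np.isscalar(R2star) else R2star
    return S0e * ad.exp(-R2e * t)


def twopool_signal(S0, f, R2a, R2b, t):
    """Two-pool GRE decay ``S0*(f*exp(-t*R2a) + (1-f)*exp(-t*R2b))``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("echo times must be nonnegative")
    fv = f.data if isinstance(f, ad.Tensor) else np.asarray(f)
    if np.any(fv < 0) or np.any(fv > 1):
        raise ValidationError("pool fraction f must lie in [0, 1]")

    def ex(x):
        return x if np.isscalar(x) else ad.expand_dims(x, -1)

    return ex(S0) * (ex(f) * ad.exp(-ex(R2a) * t) + (1.0 - ex(f)) * ad.exp(-ex(R2b) * t))


# -- model contract ------------------------------------------------------------

class ForwardModel:
    """Contract: named bounded parameters -> predicted signal.

    Subclasses define ``param_names``, ``default_bounds`` and
    :meth:`evaluate`.  ``evaluate`` must be deterministic and return an
    array shaped like the measured data (voxel leading dims + the
    measurement dims implied by the grid).
    """

    name: str = "forward_model"
    param_names: tuple[str, ...] = ()

    @property
    def default_bounds(self) -> BoundSpec:
        raise NotImplementedError

    def default_init(self, bounds: BoundSpec | None = None) -> dict[str, float]:
        """Mid-range of the bounds, the solver default when no init is given."""
        b = bounds if bounds is not None else self.default_bounds
        return {k: 0.5 * (lb + ub) for k, (lb, ub) in b.items()}

    def evaluate(self, params: dict, grid: AcquisitionGrid):
        raise NotImplementedError

    def measurement_shape(self, grid: AcquisitionGrid) -> tuple[int, ...]:
        raise NotImplementedError


class MonoExpR2s(ForwardModel):
    """Single-compartment R2* relaxometry (units: S0 arbitrary, R2* 1/ms)."""

    name = "monoexp_r2s"
    param_names = ("S0", "R2star")

    def __init__(self, s0_bounds=(0.0, 5000.0), r2s_bounds=(1e-4, 0.5)):
        self._bounds = BoundSpec({"S0": s0_bounds, "R2star": r2s_bounds})

    @property
    def default_bounds(self) -> BoundSpec:
        return self._bounds

    def evaluate(self, params, grid):
        return monoexp_signal(params["S0"], params["R2star"], grid["echo_times"])

    def measurement_shape(self, grid):
        return np.asarray(grid["echo_times"]).shape


class TwoPoolGre(ForwardModel):
    """Two-pool GRE decay; f is the fast-pool signal fraction."""

    name = "twopool_gre"
    param_names = ("S0", "f", "R2a", "R2b")

    def __init__(self):
        self._bounds = BoundSpec(
            {"S0": (0.0, 5000.0), "f": (0.0, 1.0), "R2a": (0.05, 0.5), "R2b": (1e-4, 0.05)}
        )

    @property
    def default_bounds(self) -> BoundSpec:
        return self._bounds

    def evaluate(self, params, grid):
        return twopool_signal(
            params["S0"], params["f"], params["R2a"], params["R2b"], grid["echo_times"]
        )

    def measurement_shape(self, grid):
        return np.asarray(grid["echo_times"]).shape


class GaussianMeanModel(ForwardModel):
    """Identity model: predicted signal = theta replicated over observations.

    The conjugate-Gaussian validation target for the samplers: with a
    flat prior inside wide bounds the posterior is N(ybar, sigma^2/n).
    """

    name = "gaussian_mean"
    param_names = ("theta",)

    def __init__(self, bounds=(-100.0, 100.0), n_obs: int = 1):
        self._bounds = BoundSpec({"theta": bounds})
        self.n_obs = int(n_obs)

    @property
    def default_bounds(self) -> BoundSpec:
        return self._bounds

    def evaluate(self, params, grid):
        n = int(grid["n_obs"][0]) if "n_obs" in grid else self.n_obs
        th = ad.expand_dims(params["theta"], -1)
        return th * np.ones(n)

    def measurement_shape(self, grid):
        n = int(grid["n_obs"][0]) if "n_obs" in grid else self.n_obs
        return (n,)


# -- SENSE / CAIPI encoding ----------------------------------------------------

def _check_sense_shapes(C, mask_u, spatial, n_echo):
    C = np.asarray(C)
    mask_u = np.asarray(mask_u, dtype=bool)
    if C.shape[1:] != spatial:
        raise ValidationError(f"coil map spatial shape {C.shape[1:]} != image spatial {spatial}")
    if mask_u.shape != (n_echo, *spatial):
        raise ValidationError(
            f"undersampling mask shape {mask_u.shape} != (n_echo, *spatial) {(n_echo, *spatial)}"
        )
    return C, mask_u


def sense_forward(I, C, mask_u):
    """SENSE encoding: image stack -> undersampled multi-coil k-space.

    ``I``: complex image, shape (*spatial, n_echo); ``C``: coil
    sensitivities (n_coil, *spatial); ``mask_u``: boolean k-space
    sampling mask (n_echo, *spatial).  Output shape
    (n_coil, n_echo, *spatial).  The FFT is unitary, so the adjoint of
    this operator is :func:`sense_adjoint` exactly.
    """
    Iv = I.data if isinstance(I, ad.Tensor) else np.asarray(I)
    spatial = Iv.shape[:-1]
    n_echo = Iv.shape[-1]
    C, mask_u = _check_sense_shapes(C, mask_u, spatial, n_echo)
    nd = len(spatial)
    # (n_echo, *spatial)
    Ie = ad.moveaxis(I, -1, 0)
    # (n_coil, n_echo, *spatial)
    CI = ad.expand_dims(Ie, 0) * C[:, None]
    k = ad.fftn(CI, axes=tuple(range(2, 2 + nd)))
    return k * mask_u[None]


def sense_adjoint(k, C, mask_u):
    """Adjoint of :func:`sense_forward`: k-space -> image stack."""
    kv = k.data if isinstance(k, ad.Tensor) else np.asarray(k)
    n_coil, n_echo = kv.shape[:2]
    spatial = kv.shape[2:]
    C, mask_u = _check_sense_shapes(C, mask_u, spatial, n_echo)
    nd = len(spatial)
    km = k * mask_u[None]
    img = ad.ifftn(km, axes=tuple(range(2, 2 + nd)))
    coil_sum = ad.sum(img * np.conj(C)[:, None], axis=0)  # (n_echo, *spatial)
    return ad.moveaxis(coil_sum, 0, -1)


class SenseModel(ForwardModel):
    """SENSE/CAIPI encoding as a ForwardModel over the unknown image.

    The unknown complex image is carried as two real parameter maps
    ``I_real`` and ``I_imag`` of shape (*spatial, n_echo); they are
    unbounded (identity parametrisation in the solver).  The grid must
    provide nothing — coil maps and the sampling mask are operator state.
    """

    name = "sense"
    param_names = ("I_real", "I_imag")

    def __init__(self, C: np.ndarray, mask_u: np.ndarray):
        self.C = np.asarray(C, dtype=complex)
        self.mask_u = np.asarray(mask_u, dtype=bool)

    @property
    def default_bounds(self) -> BoundSpec | None:
        return None  # unbounded unknowns

    def evaluate(self, params, grid):
        I = params["I_real"] + params["I_imag"] * 1j
        return sense_forward(I, self.C, self.mask_u)

    def measurement_shape(self, grid):
        return (self.C.shape[0], *self.mask_u.shape)


# -- registry ------------------------------------------------------------------

_REGISTRY: dict[str, object] = {}


def register_model(name: str, model) -> None:
    """Register a model instance or factory under a unique name."""
    if name in _REGISTRY:
        raise ValidationError(f"model {name!r} already registered")
    _REGISTRY[name] = model


def get_model(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> list[str]:
    return sorted(_REGISTRY)


register_model("monoexp_r2s", MonoExpR2s())
register_model("twopool_gre", TwoPoolGre())
register_model("gaussian_mean", GaussianMeanModel())
register_model("sense", SenseModel)  # factory: needs coil maps + sampling mask
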