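"""Whole-volume gradient-descent solver.

Instead of fitting each voxel independently, the solver poses one global
objective over every masked voxel,

    argmin_theta  || M . W (S_meas - S(phi, theta)) ||_{L1|L2} + sum_k lambda_k R_k(theta),

and minimises it with a first-order optimiser (Adam, SGD+momentum, or
RMSProp) using reverse-mode automatic differentiation.  Gradients are
taken in unconstrained (scaled-logit) space so box bounds hold by
construction at every iterate.

Three stopping criteria, checked each iteration in the order
tol -> max-iteration -> convergence slope:

* loss below ``tol``;
* iteration count reaching ``iteration``;
* |OLS slope of the loss over the last ``convergence_window``
  iterations| below ``convergence_value``.

Execution is deterministic: the full masked volume is evaluated every
iteration (no minibatching), so repeated runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .core import (
    BoundSpec,
    ValidationError,
    from_unconstrained,
    gather,
    scatter,
    to_unconstrained,
    validate_inputs,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "OptimizerState",
    "adam_step",
    "convergence_slope",
    "data_loss",
    "fit",
    "recon_askadam",
    "rmsprop_step",
    "sgdm_step",
]


@dataclass
class FitOptions:
    """Solver options (names follow the framework's option vocabulary)."""

    optimizer: str = "adam"  # adam | sgdm | rmsprop
    initial_learn_rate: float = 0.001
    iteration: int = 4000
    tol: float = 1e-12
    convergence_value: float = 1e-8
    convergence_window: int = 20
    loss_function: str = "l1"  # l1 | l2
    optimise_memory: bool = True
    verbose: bool = False

    def __post_init__(self):
        if self.iteration < 1:
            raise ValidationError("iteration must be >= 1")
        if self.convergence_window <= 1:
            raise ValidationError("convergence_window must be > 1")
        if self.initial_learn_rate <= 0:
            raise ValidationError("learn rate must be > 0")
        if self.optimizer not in ("adam", "sgdm", "rmsprop"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_function not in ("l1", "l2"):
            raise ValidationError(f"unknown loss function {self.loss_function!r}")


@dataclass
class OptimizerState:
    """First/second-moment accumulators, shaped like the parameters."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def zeros_like(cls, params: dict[str, np.ndarray]) -> "OptimizerState":
        return cls(
            m={k: np.zeros_like(v) for k, v in params.items()},
            v={k: np.zeros_like(v) for k, v in params.items()},
            t=0,
        )


@dataclass
class FitResult:
    final: dict[str, np.ndarray]
    loss_history: np.ndarray
    termination: str  # tol | max_iter | converged
    iterations: int
    extras: dict = field(default_factory=dict)


# -- loss ----------------------------------------------------------------------

def data_loss(s_meas, s_pred, mask=None, weights=None, norm: str = "l2"):
    """Mean over masked elements of |W r| (l1) or (W r)^2 (l2).

    Complex residuals use the complex modulus.  ``mask`` has spatial
    shape and broadcasts over trailing measurement dims; pass ``None``
    when the inputs are already restricted to masked voxels.
    """
    if norm not in ("l1", "l2"):
        raise ValidationError(f"unknown norm {norm!r}")
    r = s_meas - s_pred
    if weights is not None:
        r = r * weights
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError("mask has no True voxels")
        r = ad.getitem(r, mask) if isinstance(r, ad.Tensor) else np.asarray(r)[mask]
    a = ad.absolute(r)
    if norm == "l2":
        a = ad.square(a)
    return ad.mean(a)


# -- optimiser steps -----------------------------------------------------------

def _check_finite(grads: dict[str, np.ndarray]) -> None:
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {name!r}")


def adam_step(state, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    """One Adam update; returns (new_state, update dict to subtract)."""
    _check_finite(grads)
    t = state.t + 1
    m, v, upd = {}, {}, {}
    for k, g in grads.items():
        m[k] = beta1 * state.m[k] + (1 - beta1) * g
        v[k] = beta2 * state.v[k] + (1 - beta2) * np.abs(g) ** 2
        mhat = m[k] / (1 - beta1**t)
        vhat = v[k] / (1 - beta2**t)
        upd[k] = lr * mhat / (np.sqrt(vhat) + eps)
    return OptimizerState(m, v, t), upd


def sgdm_step(state, grads, lr, momentum=0.9):
    """SGD with momentum: velocity = momentum*velocity + g; step = lr*velocity."""
    _check_finite(grads)
    m, upd = {}, {}
    for k, g in grads.items():
        m[k] = momentum * state.m[k] + g
        upd[k] = lr * m[k]
    return OptimizerState(m, state.v, state.t + 1), upd


def rmsprop_step(state, grads, lr, decay=0.9, eps=1e-8):
    """RMSProp: v = decay*v + (1-decay)*g^2; step = lr*g/(sqrt(v)+eps)."""
    _check_finite(grads)
    v, upd = {}, {}
    for k, g in grads.items():
        v[k] = decay * state.v[k] + (1 - decay) * np.abs(g) ** 2
        upd[k] = lr * g / (np.sqrt(v[k]) + eps)
    return OptimizerState(state.m, v, state.t + 1), upd


_STEPPERS = {"adam": adam_step, "sgdm": sgdm_step, "rmsprop": rmsprop_step}


# -- convergence ---------------------------------------------------------------

def convergence_slope(loss_history, window: int):
    """OLS slope of loss vs iteration over the last ``window`` entries.

    Returns None ("not yet evaluable") while the history is shorter than
    the window.
    """
    if window <= 1:
        raise ValidationError("window must be > 1")
    h = np.asarray(loss_history, dtype=float)
    if h.size < window:
        return None
    y = h[-window:]
    x = np.arange(window, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


# -- the fit loop --------------------------------------------------------------

def fit(
    model,
    signal,
    mask=None,
    weights=None,
    grid=None,
    init=None,
    bounds=None,
    options: FitOptions | None = None,
    regularizer=None,
    layout: str = "volume",
) -> FitResult:
    """Whole-volume fit of ``model`` to ``signal``; returns final maps.

    ``init`` maps parameter names to scalars or arrays (default:
    mid-range of bounds); ``regularizer`` is a callable
    ``params_dict -> scalar`` (e.g. from :func:`qmrifit.regularizers.compose`)
    evaluated on the parameters **in volume layout** so spatial terms see
    neighbourhoods even when the loss itself runs on gathered voxels.
    """
    opts = options or FitOptions()
    bundle = validate_inputs(signal, mask, weights, grid, layout=layout)
    bounds = bounds if bounds is not None else model.default_bounds
    mask_b = bundle.mask
    n_masked = int(mask_b.sum())

    # initial parameter maps over masked voxels (flat) and their volume shape
    spatial_shape = mask_b.shape
    if init is None:
        init = model.default_init(bounds) if bounds is not None else None
        if init is None:
            raise ValidationError("init is required for unbounded models")
    init_flat = {}
    for name in model.param_names:
        val = init[name]
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_masked, float(arr))
        else:
            if arr.shape[: len(spatial_shape)] == spatial_shape:
                arr = gather(arr, mask_b)
            elif arr.shape[0] != n_masked:
                raise ValidationError(f"init for {name!r} has incompatible shape {arr.shape}")
        init_flat[name] = arr

    if bounds is not None:
        z = to_unconstrained(init_flat, bounds)
    else:
        z = {k: v.copy() for k, v in init_flat.items()}

    sig_flat = gather(bundle.signal, mask_b)
    w_flat = gather(bundle.weights, mask_b)

    # shape check before iteration 1
    theta0 = from_unconstrained({k: v for k, v in z.items()}, bounds)
    pred0 = model.evaluate(theta0, bundle.grid)
    pred0 = pred0.data if isinstance(pred0, ad.Tensor) else np.asarray(pred0)
    if pred0.shape != sig_flat.shape:
        raise ValidationError(
            f"model output shape {pred0.shape} != masked signal shape {sig_flat.shape}"
        )

    stepper = _STEPPERS[opts.optimizer]
    state = OptimizerState.zeros_like(z)
    loss_history = []
    termination = "max_iter"
    last_good = {k: v.copy() for k, v in z.items()}

    for it in range(1, opts.iteration + 1):
        leaves = {k: ad.Tensor(v, requires_grad=True) for k, v in z.items()}
        theta = from_unconstrained(leaves, bounds)
        pred = model.evaluate(theta, bundle.grid)
        loss = data_loss(sig_flat, pred, mask=None, weights=w_flat, norm=opts.loss_function)
        if regularizer is not None:
            theta_vol = {
                k: _scatter_tensor(v, mask_b) for k, v in theta.items()
            }
            reg = regularizer(theta_vol)
            loss = loss + reg if isinstance(reg, ad.Tensor) else loss + float(reg)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            warnings.warn("non-finite loss; aborting with last good state", stacklevel=2)
            z = last_good
            termination = "aborted"
            break
        last_good = {k: v.copy() for k, v in z.items()}
        loss.backward()
        grads = {k: leaves[k].grad for k in z}
        state, upd = stepper(state, grads, opts.initial_learn_rate)
        z = {k: z[k] - upd[k] for k in z}
        loss_history.append(loss_val)

        # stopping criteria: tol -> max_iter -> slope
        if loss_val < opts.tol:
            termination = "tol"
            break
        if it == opts.iteration:
            termination = "max_iter"
            break
        slope = convergence_slope(loss_history, opts.convergence_window)
        if slope is not None and abs(slope) < opts.convergence_value:
            termination = "converged"
            break

    theta_final_flat = from_unconstrained(z, bounds)
    final = {k: scatter(np.asarray(v), mask_b, fill=np.nan) for k, v in theta_final_flat.items()}
    return FitResult(
        final=final,
        loss_history=np.asarray(loss_history),
        termination=termination,
        iterations=len(loss_history),
        extras={"final_flat": {k: np.asarray(v) for k, v in theta_final_flat.items()}},
    )


def _scatter_tensor(flat, mask):
    """Scatter a flat per-voxel Tensor back to volume layout (fill 0)."""
    if not isinstance(flat, ad.Tensor):
        return scatter(np.asarray(flat), mask, fill=0.0)
    from .core import mask_flat_indices

    idx = mask_flat_indices(mask)
    n = mask.size
    trailing = flat.data.shape[1:]
    zero = ad.Tensor(np.zeros((n, *trailing)))
    # scatter via index assignment is not a tape op; build with getitem's adjoint:
    # out[idx] = flat  <=>  out = scatter-add of flat at idx
    out = _scatter_add(flat, idx, n)
    return ad.reshape(out, (*mask.shape, *trailing))


def _scatter_add(flat: ad.Tensor, idx: np.ndarray, n: int) -> ad.Tensor:
    val = np.zeros((n, *flat.data.shape[1:]), dtype=flat.data.dtype)
    val[idx] = flat.data
    return ad.Tensor(
        val,
        requires_grad=True,
        _parents=(flat,),
        _vjps=(lambda g: g[idx],),
    )


# -- SENSE/CAIPI reconstruction application ------------------------------------

def recon_askadam(
    k,
    C,
    mask_u,
    lam_tv: float = 0.0,
    lam_l2: float = 0.0,
    loss_function: str = "l2",
    options: FitOptions | None = None,
    init=None,
) -> FitResult:
    """Reconstruct a complex multi-echo image from undersampled k-space.

    Minimises ``mean |k - E I|^p + lam_tv * TV2D(I) + lam_l2 * mean |I|^2``
    over the complex image ``I`` (carried as real/imaginary maps,
    identity parametrisation) with the same optimiser loop as the voxel
    fits.  TV is applied slice-wise (2D) to the real and imaginary
    parts; the optional Tikhonov term tames the weakly-encoded
    directions of highly accelerated acquisitions.  ``init`` defaults to
    the adjoint reconstruction ``E^H k``.
    """
    from .models import sense_adjoint, sense_forward
    from .regularizers import tv_spatial

    opts = options or FitOptions(iteration=500, initial_learn_rate=0.01, loss_function=loss_function)
    k = np.asarray(k, dtype=complex)
    if init is None:
        init = sense_adjoint(k, C, mask_u)
    z = {"I_real": np.ascontiguousarray(init.real), "I_imag": np.ascontiguousarray(init.imag)}
    state = OptimizerState.zeros_like(z)
    stepper = _STEPPERS[opts.optimizer]
    loss_history = []
    termination = "max_iter"

    for it in range(1, opts.iteration + 1):
        leaves = {key: ad.Tensor(v, requires_grad=True) for key, v in z.items()}
        I = leaves["I_real"] + leaves["I_imag"] * 1j
        pred = sense_forward(I, C, mask_u)
        loss = data_loss(k, pred, mask=None, weights=None, norm=opts.loss_function)
        if lam_tv > 0:
            loss = loss + lam_tv * (
                tv_spatial(leaves["I_real"], ndims=2) + tv_spatial(leaves["I_imag"], ndims=2)
            )
        if lam_l2 > 0:
            loss = loss + lam_l2 * ad.mean(ad.absolute(I) ** 2)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            warnings.warn("non-finite recon loss; stopping", stacklevel=2)
            termination = "aborted"
            break
        loss.backward()
        grads = {key: leaves[key].grad for key in z}
        state, upd = stepper(state, grads, opts.initial_learn_rate)
        z = {key: z[key] - upd[key] for key in z}
        loss_history.append(loss_val)
        if loss_val < opts.tol:
            termination = "tol"
            break
        if it == opts.iteration:
            termination = "max_iter"
            break
        slope = convergence_slope(loss_history, opts.convergence_window)
        if slope is not None and abs(slope) < opts.convergence_value:
            termination = "converged"
            break

    image = z["I_real"] + 1j * z["I_imag"]
    return FitResult(
        final={"image": image},
        loss_history=np.asarray(loss_history),
        termination=termination,
        iterations=len(loss_history),
    )
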