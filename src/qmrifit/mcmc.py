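"""Vectorised MCMC solvers: Metropolis-Hastings and affine-invariant ensemble.

Both samplers share the gradient solver's forward-model contract and a
Gaussian likelihood with fixed, user-supplied noise SD.  Box bounds act
as a truncated-uniform prior: proposals with any parameter outside the
bounds are rejected, which preserves proposal symmetry.

All masked voxels (and all chains/walkers per voxel) advance in lockstep
vectorised iterations.  Randomness is organised so the vectorised
implementation is **bit-identical** to a per-voxel sequential loop: one
master seed spawns an independent substream per voxel
(``numpy.random.SeedSequence.spawn``), and each voxel's stream is
consumed in a fixed documented block order:

* MH: [optional init jitter] -> proposal normals (iteration, chains,
  params) -> acceptance uniforms (iteration, chains);
* ensemble: walker-init jitter (walkers, params) -> stretch uniforms
  (iteration, walkers) -> complementary-walker indices (iteration,
  walkers) -> acceptance uniforms (iteration, walkers).

Chain accounting: per chain the first ``floor(burnin * iteration)``
states are discarded and every ``thinning``-th of the remainder is kept,
giving ``floor((1 - burnin) * iteration / thinning)`` retained samples
per chain — e.g. 4 chains x 25000 iterations at 10% burn-in, thinning
100 -> 900 samples, as does 50 walkers x 2000 iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BoundSpec, ValidationError, gather, scatter, validate_inputs

__all__ = [
    "ChainStore",
    "McmcOptions",
    "PosteriorSummary",
    "ensemble_sample",
    "log_likelihood",
    "mh_sample",
    "retain",
    "summarize",
]


@dataclass
class McmcOptions:
    algorithm: str = "mh"  # mh | ensemble
    iteration: int = 25000
    burnin: float = 0.1
    thinning: int = 100
    x_step_size: dict[str, float] | float | None = None  # MH proposal SD per parameter
    step_size: float = 2.0  # ensemble stretch parameter a
    n_walkers: int = 50
    n_proposals: int = 4  # independent MH chains per voxel
    noise_sd: float | np.ndarray = 1.0  # Gaussian likelihood sigma (scalar or per-voxel)
    seed: int = 0

    def __post_init__(self):
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")
        if not 0 <= self.burnin < 1:
            raise ValidationError("burnin must be in [0, 1)")
        if self.algorithm not in ("mh", "ensemble"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "ensemble":
            if self.n_walkers % 2 != 0 or self.n_walkers < 4:
                raise ValidationError("n_walkers must be even and >= 4")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValidationError("noise_sd must be > 0")
        if self.step_size <= 1:
            raise ValidationError("ensemble stretch parameter must be > 1")


@dataclass
class ChainStore:
    """Retained posterior samples: (voxel, chain_or_walker, sample, param)."""

    samples: np.ndarray
    param_names: tuple[str, ...]
    kept_iterations: np.ndarray  # chain state indices that were retained
    acceptance_rate: np.ndarray  # (voxel, chain_or_walker)

    @property
    def n_retained(self) -> int:
        """Total retained samples per voxel (chains x per-chain count)."""
        return self.samples.shape[1] * self.samples.shape[2]


@dataclass
class PosteriorSummary:
    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    iqr: dict[str, np.ndarray] = field(default_factory=dict)


# -- likelihood ----------------------------------------------------------------

def log_likelihood(s_meas, s_pred, sigma):
    """Gaussian log-likelihood per voxel, additive constants dropped:
    ``-sum_measurements r^2 / (2 sigma^2)`` with ``r = s_meas - s_pred``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be > 0")
    r = np.asarray(s_meas) - np.asarray(s_pred)
    return -0.5 * np.sum(r * r, axis=-1) / (sigma * sigma)


# -- chain accounting ----------------------------------------------------------

def retain(iteration: int, burnin: float, thinning: int, n_chains: int):
    """Retention rule; returns (total retained, per-chain kept state indices).

    Per chain: discard the first ``floor(burnin * iteration)`` states,
    then keep every ``thinning``-th of the remainder (the states at
    offsets thinning, 2*thinning, ... past the burn-in).
    """
    if thinning < 1 or not 0 <= burnin < 1 or iteration < 1 or n_chains < 1:
        raise ValidationError("invalid retention settings")
    burn = int(np.floor(burnin * iteration))
    idx = np.arange(burn + thinning - 1, iteration, thinning)
    if idx.size == 0:
        raise ValidationError(
            f"no samples retained (iteration={iteration}, burnin={burnin}, "
            f"thinning={thinning}); increase iteration or reduce thinning"
        )
    return int(idx.size) * int(n_chains), idx


# -- shared machinery ----------------------------------------------------------

def _prepare(model, signal, mask, grid, init, bounds, options, layout):
    bundle = validate_inputs(signal, mask, grid=grid, layout=layout)
    sig = gather(bundle.signal, bundle.mask)
    sig = sig.reshape(sig.shape[0], -1)  # flatten measurement dims
    V = sig.shape[0]
    bounds = bounds if bounds is not None else model.default_bounds
    names = tuple(model.param_names)
    P = len(names)
    if init is None:
        init = model.default_init(bounds)
    theta0 = np.empty((V, P))
    for pi, name in enumerate(names):
        val = np.asarray(init[name], dtype=float)
        if val.ndim == 0:
            theta0[:, pi] = float(val)
        elif val.shape[: bundle.mask.ndim] == bundle.mask.shape:
            theta0[:, pi] = gather(val, bundle.mask)
        else:
            theta0[:, pi] = val.reshape(V)
    lb = np.array([bounds[n][0] for n in names])
    ub = np.array([bounds[n][1] for n in names])
    sigma = np.asarray(options.noise_sd, dtype=float)
    if sigma.ndim > 0:
        if sigma.shape[: bundle.mask.ndim] == bundle.mask.shape:
            sigma = gather(sigma, bundle.mask)
        sigma = sigma.reshape(V, 1)
    return bundle, sig, V, names, P, theta0, lb, ub, sigma


def _make_loglik(model, grid, names, sig, sigma):
    """Per-(voxel, chain) log-likelihood; identical arithmetic for the
    vectorised and sequential paths (sequential passes V=1 slices)."""

    sig2 = np.asarray(sigma) ** 2  # scalar or (V, 1), broadcasts over chains

    def loglik(theta):  # theta: (V, C, P)
        params = {name: theta[..., pi] for pi, name in enumerate(names)}
        pred = np.asarray(model.evaluate(params, grid))
        pred = pred.reshape(theta.shape[0], theta.shape[1], -1)
        r = sig[:, None, :] - pred
        return -0.5 * np.sum(r * r, axis=-1) / sig2

    return loglik


# -- Metropolis-Hastings -------------------------------------------------------

def _mh_streams(seed, n_voxels, iteration, n_chains, n_params):
    """Per-voxel random blocks in the documented consumption order."""
    children = np.random.SeedSequence(seed).spawn(n_voxels)
    normals = np.empty((n_voxels, iteration, n_chains, n_params))
    uniforms = np.empty((n_voxels, iteration, n_chains))
    for v, child in enumerate(children):
        rng = np.random.default_rng(child)
        normals[v] = rng.standard_normal((iteration, n_chains, n_params))
        uniforms[v] = rng.random((iteration, n_chains))
    return normals, uniforms


def mh_sample(
    model, signal, mask=None, grid=None, init=None, bounds=None,
    options: McmcOptions | None = None, layout="volume", _voxel_slice=None,
) -> ChainStore:
    """Vectorised Metropolis-Hastings over all masked voxels.

    Runs ``n_proposals`` independent chains per voxel with symmetric
    normal proposals of SD ``x_step_size`` per parameter; out-of-bounds
    proposals are rejected.  ``_voxel_slice`` restricts the computation
    to a subset of voxels *with unchanged substreams* — the sequential
    bit-identity reference loops voxels through it.
    """
    opts = options or McmcOptions()
    bundle, sig, V, names, P, theta0, lb, ub, sigma = _prepare(
        model, signal, mask, grid, init, bounds, opts, layout
    )
    C = int(opts.n_proposals)
    step = _step_vector(opts.x_step_size, names, lb, ub)
    _, kept = retain(opts.iteration, opts.burnin, opts.thinning, C)

    normals, uniforms = _mh_streams(opts.seed, V, opts.iteration, C, P)
    if _voxel_slice is not None:
        vs = _voxel_slice
        sig, theta0 = sig[vs], theta0[vs]
        normals, uniforms = normals[vs], uniforms[vs]
        if sigma.ndim == 2:
            sigma = sigma[vs]
        V = sig.shape[0]

    loglik = _make_loglik(model, bundle.grid, names, sig, sigma)
    theta = np.broadcast_to(theta0[:, None, :], (V, C, P)).copy()
    ll = loglik(theta)
    samples = np.empty((V, C, kept.size, P))
    accepted = np.zeros((V, C))
    kept_set = {int(i): k for k, i in enumerate(kept)}

    for i in range(opts.iteration):
        prop = theta + step * normals[:, i]
        inb = np.all((prop > lb) & (prop < ub), axis=-1)
        prop_eval = np.where(inb[..., None], prop, theta)  # keep model inputs valid
        ll_prop = loglik(prop_eval)
        accept = inb & (np.log(uniforms[:, i]) < (ll_prop - ll))
        theta = np.where(accept[..., None], prop, theta)
        ll = np.where(accept, ll_prop, ll)
        accepted += accept
        if i == 999 and not accepted.any():
            warnings.warn(
                "no proposals accepted in the first 1000 iterations; "
                f"acceptance rates are all 0 (step sizes: {dict(zip(names, step))})",
                stacklevel=2,
            )
        k = kept_set.get(i)
        if k is not None:
            samples[:, :, k, :] = theta

    return ChainStore(
        samples=samples,
        param_names=names,
        kept_iterations=kept,
        acceptance_rate=accepted / opts.iteration,
    )


def mh_sample_reference(model, signal, mask=None, grid=None, init=None, bounds=None,
                        options: McmcOptions | None = None, layout="volume") -> ChainStore:
    """Sequential per-voxel MH loop; bit-identical oracle for :func:`mh_sample`."""
    opts = options or McmcOptions()
    bundle = validate_inputs(signal, mask, grid=grid, layout=layout)
    V = int(bundle.mask.sum())
    stores = [
        mh_sample(model, signal, mask, grid, init, bounds, opts, layout,
                  _voxel_slice=slice(v, v + 1))
        for v in range(V)
    ]
    return ChainStore(
        samples=np.concatenate([s.samples for s in stores], axis=0),
        param_names=stores[0].param_names,
        kept_iterations=stores[0].kept_iterations,
        acceptance_rate=np.concatenate([s.acceptance_rate for s in stores], axis=0),
    )


def _step_vector(x_step_size, names, lb, ub):
    if x_step_size is None:
        return 0.05 * (ub - lb)  # 5% of the bound range per parameter
    if isinstance(x_step_size, dict):
        missing = set(names) - set(x_step_size)
        if missing:
            raise ValidationError(f"x_step_size missing entries for {sorted(missing)}")
        return np.array([float(x_step_size[n]) for n in names])
    arr = np.asarray(x_step_size, dtype=float)
    if arr.ndim == 0:
        return np.full(len(names), float(arr))
    if arr.shape != (len(names),):
        raise ValidationError("x_step_size needs one entry per parameter")
    return arr


# -- affine-invariant ensemble -------------------------------------------------

def _ensemble_streams(seed, n_voxels, iteration, n_walkers, n_params):
    children = np.random.SeedSequence(seed).spawn(n_voxels)
    jitter = np.empty((n_voxels, n_walkers, n_params))
    z_u = np.empty((n_voxels, iteration, n_walkers))
    pair = np.empty((n_voxels, iteration, n_walkers), dtype=np.int64)
    acc_u = np.empty((n_voxels, iteration, n_walkers))
    half = n_walkers // 2
    for v, child in enumerate(children):
        rng = np.random.default_rng(child)
        jitter[v] = rng.uniform(-1.0, 1.0, (n_walkers, n_params))
        z_u[v] = rng.random((iteration, n_walkers))
        pair[v] = rng.integers(0, half, (iteration, n_walkers))
        acc_u[v] = rng.random((iteration, n_walkers))
    return jitter, z_u, pair, acc_u


def ensemble_sample(
    model, signal, mask=None, grid=None, init=None, bounds=None,
    options: McmcOptions | None = None, layout="volume", _voxel_slice=None,
) -> ChainStore:
    """Affine-invariant ensemble (stretch-move) sampler per voxel.

    Walkers are split into two halves updated alternately.  For walker k
    with complementary walker j from the other half, the stretch factor
    z has density proportional to 1/sqrt(z) on [1/a, a] (drawn as
    ``z = ((a-1)u + 1)^2 / a``), the proposal is
    ``Y = X_j + z (X_k - X_j)``, and the log-acceptance is
    ``(d-1) log z + delta log-likelihood``.
    """
    opts = options or McmcOptions(algorithm="ensemble", iteration=2000)
    bundle, sig, V, names, P, theta0, lb, ub, sigma = _prepare(
        model, signal, mask, grid, init, bounds, opts, layout
    )
    W = int(opts.n_walkers)
    a = float(opts.step_size)
    if W < 2 * P:
        warnings.warn(
            f"n_walkers={W} < 2 x n_params={2 * P}: degenerate ensemble geometry",
            stacklevel=2,
        )
    _, kept = retain(opts.iteration, opts.burnin, opts.thinning, W)

    jitter, z_u, pair, acc_u = _ensemble_streams(opts.seed, V, opts.iteration, W, P)
    if _voxel_slice is not None:
        vs = _voxel_slice
        sig, theta0 = sig[vs], theta0[vs]
        jitter, z_u, pair, acc_u = jitter[vs], z_u[vs], pair[vs], acc_u[vs]
        if sigma.ndim == 2:
            sigma = sigma[vs]
        V = sig.shape[0]

    eps = 1e-9 * (ub - lb)
    walkers = theta0[:, None, :] + jitter * 0.01 * (ub - lb)
    walkers = np.clip(walkers, lb + eps, ub - eps)  # strictly inside bounds
    if np.any(np.ptp(walkers, axis=1).max(axis=-1) == 0):
        raise ValidationError("ensemble walkers are identical at init; nonzero spread required")

    loglik = _make_loglik(model, bundle.grid, names, sig, sigma)
    ll = loglik(walkers)  # (V, W)
    half = W // 2
    halves = (np.arange(0, half), np.arange(half, W))
    samples = np.empty((V, W, kept.size, P))
    accepted = np.zeros((V, W))
    kept_set = {int(i): k for k, i in enumerate(kept)}

    for i in range(opts.iteration):
        for h, own in enumerate(halves):
            other = halves[1 - h]
            u = z_u[:, i, own]
            z = ((a - 1.0) * u + 1.0) ** 2 / a  # density ~ 1/sqrt(z) on [1/a, a]
            j = pair[:, i, own]  # index into the complementary half
            comp = np.take_along_axis(
                walkers[:, other, :], j[..., None], axis=1
            )  # (V, half, P)
            own_x = walkers[:, own, :]
            prop = comp + z[..., None] * (own_x - comp)
            inb = np.all((prop > lb) & (prop < ub), axis=-1)
            prop_eval = np.where(inb[..., None], prop, own_x)
            ll_prop = loglik(prop_eval)
            log_acc = (P - 1) * np.log(z) + ll_prop - ll[:, own]
            accept = inb & (np.log(acc_u[:, i, own]) < log_acc)
            walkers[:, own, :] = np.where(accept[..., None], prop, own_x)
            ll[:, own] = np.where(accept, ll_prop, ll[:, own])
            accepted[:, own] += accept
        k = kept_set.get(i)
        if k is not None:
            samples[:, :, k, :] = walkers

    return ChainStore(
        samples=samples,
        param_names=names,
        kept_iterations=kept,
        acceptance_rate=accepted / opts.iteration,
    )


def ensemble_sample_reference(model, signal, mask=None, grid=None, init=None, bounds=None,
                              options: McmcOptions | None = None, layout="volume") -> ChainStore:
    """Sequential per-voxel ensemble loop; bit-identity oracle."""
    opts = options or McmcOptions(algorithm="ensemble", iteration=2000)
    bundle = validate_inputs(signal, mask, grid=grid, layout=layout)
    V = int(bundle.mask.sum())
    stores = [
        ensemble_sample(model, signal, mask, grid, init, bounds, opts, layout,
                        _voxel_slice=slice(v, v + 1))
        for v in range(V)
    ]
    return ChainStore(
        samples=np.concatenate([s.samples for s in stores], axis=0),
        param_names=stores[0].param_names,
        kept_iterations=stores[0].kept_iterations,
        acceptance_rate=np.concatenate([s.acceptance_rate for s in stores], axis=0),
    )


# -- summaries -----------------------------------------------------------------

def summarize(chains: ChainStore, mask=None, with_iqr: bool = False) -> PosteriorSummary:
    """Per-voxel posterior mean and SD (unbiased, n-1) per parameter.

    If ``mask`` is given, per-voxel vectors are scattered back to volume
    layout (NaN fill outside the mask).
    """
    V, C, K, P = chains.samples.shape
    if C * K < 2:
        raise ValidationError("need at least 2 retained samples per voxel")
    flat = chains.samples.reshape(V, C * K, P)
    mean, std, iqr = {}, {}, {}
    for pi, name in enumerate(chains.param_names):
        s = flat[:, :, pi]
        mu = s.mean(axis=1)
        sd = s.std(axis=1, ddof=1)
        mean[name] = scatter(mu, mask, fill=np.nan) if mask is not None else mu
        std[name] = scatter(sd, mask, fill=np.nan) if mask is not None else sd
        if with_iqr:
            q = np.percentile(s, [25, 75], axis=1)
            r = q[1] - q[0]
            iqr[name] = scatter(r, mask, fill=np.nan) if mask is not None else r
    return PosteriorSummary(mean=mean, std=std, iqr=iqr)
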