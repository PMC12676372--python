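"""Synthetic-data generators, the per-voxel NLLS reference oracle, and the
conjugate-gradient SENSE baseline.

Every generator is a pure function of its seed and settings.  Noise is
additive Gaussian on the magnitude signal (matching the samplers'
Gaussian likelihood); SNR is anchored at the reference measurement:
``noise_sd = mean(noise-free signal at the first echo, inside the mask) / SNR``.
A Rician option exists for realism studies but is off by default.

Phantom geometry is piecewise constant (nested boxes/ellipses), which
gives total-variation regularisation a truthful target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse.linalg

from .core import AcquisitionGrid, BoundSpec, ValidationError, gather, scatter
from .models import monoexp_signal, sense_adjoint, sense_forward, twopool_signal

__all__ = [
    "PhantomRecon",
    "SyntheticTruth",
    "caipi_mask",
    "gen_gaussian_toy",
    "gen_monoexp_volume",
    "gen_phantom_recon",
    "gen_twopool_volume",
    "lsqr_baseline",
    "nlls_oracle",
]


@dataclass
class SyntheticTruth:
    truth: dict[str, np.ndarray]
    signal_clean: np.ndarray
    signal: np.ndarray
    mask: np.ndarray
    grid: AcquisitionGrid
    noise_sd: float
    snr: float
    seed: int


@dataclass
class PhantomRecon:
    image: np.ndarray  # complex truth, (*spatial, n_echo)
    coils: np.ndarray  # (n_coil, *spatial), sum_c |C|^2 = 1 per voxel
    mask_u: np.ndarray  # (n_echo, *spatial) boolean
    kspace: np.ndarray  # (n_coil, n_echo, *spatial), undersampled + noisy
    grid: AcquisitionGrid
    noise_sd: float
    seed: int


def _piecewise_maps(shape, ranges, rng, n_blocks=4):
    """Piecewise-constant maps: nested boxes with values drawn per block."""
    maps = {k: np.full(shape, 0.5 * (lo + hi)) for k, (lo, hi) in ranges.items()}
    nx, ny, nz = shape
    for b in range(n_blocks):
        # shrinking nested boxes
        fx = int(nx * (b + 1) / (2 * n_blocks))
        fy = int(ny * (b + 1) / (2 * n_blocks))
        fz = int(nz * (b + 1) / (2 * n_blocks))
        sl = (slice(fx, nx - fx or None), slice(fy, ny - fy or None), slice(fz, nz - fz or None))
        for k, (lo, hi) in ranges.items():
            maps[k][sl] = rng.uniform(lo, hi)
    return maps


def _smooth_maps(shape, ranges, rng):
    """Smoothly varying maps: low-frequency random fields scaled into range."""
    maps = {}
    x, y, z = np.meshgrid(*[np.linspace(0, 1, n) for n in shape], indexing="ij")
    for k, (lo, hi) in ranges.items():
        a, b, c, d = rng.uniform(-1, 1, 4)
        f = np.sin(np.pi * (a * x + b * y + c * z) + d)
        f = (f - f.min()) / max(np.ptp(f), 1e-12)
        maps[k] = lo + (hi - lo) * (0.1 + 0.8 * f)
    return maps


def _add_noise(clean, mask, snr, rng, rician=False):
    ref = float(np.mean(clean[mask][..., 0]))
    sd = ref / snr
    noise = rng.standard_normal(clean.shape) * sd
    if rician:
        noise_i = rng.standard_normal(clean.shape) * sd
        noisy = np.sqrt((clean + noise) ** 2 + noise_i**2)
    else:
        noisy = clean + noise
    return noisy, sd


def gen_monoexp_volume(
    shape=(8, 8, 8),
    s0_range=(500.0, 2000.0),
    r2s_range=(0.01, 0.05),
    echo_times=None,
    snr=50.0,
    seed=0,
    mode="piecewise",
    rician=False,
) -> SyntheticTruth:
    """Mono-exponential R2* volume at a stated SNR (anchored at TE1)."""
    if snr <= 0:
        raise ValidationError("SNR must be > 0")
    if s0_range[0] >= s0_range[1] or r2s_range[0] >= r2s_range[1]:
        raise ValidationError("degenerate parameter range")
    if echo_times is None:
        echo_times = np.arange(2.0, 25.0, 2.0)  # 12 echoes, 2..24 ms
    rng = np.random.default_rng(seed)
    ranges = {"S0": s0_range, "R2star": r2s_range}
    gen = _piecewise_maps if mode == "piecewise" else _smooth_maps
    truth = gen(shape, ranges, rng)
    mask = np.ones(shape, dtype=bool)
    clean = np.asarray(monoexp_signal(truth["S0"], truth["R2star"], echo_times))
    noisy, sd = _add_noise(clean, mask, snr, rng, rician)
    return SyntheticTruth(
        truth, clean, noisy, mask, AcquisitionGrid({"echo_times": echo_times}), sd, snr, seed
    )


def gen_twopool_volume(
    shape=(8, 8, 8),
    ranges=None,
    echo_times=None,
    snr=100.0,
    seed=0,
    mode="piecewise",
    rician=False,
) -> SyntheticTruth:
    """Two-pool GRE volume — an ill-conditioned regularisation demo."""
    if snr <= 0:
        raise ValidationError("SNR must be > 0")
    if ranges is None:
        ranges = {
            "S0": (800.0, 1200.0),
            "f": (0.1, 0.4),
            "R2a": (0.08, 0.15),
            "R2b": (0.01, 0.03),
        }
    if echo_times is None:
        echo_times = np.arange(2.0, 49.0, 2.0)  # 24 echoes to separate the pools
    rng = np.random.default_rng(seed)
    gen = _piecewise_maps if mode == "piecewise" else _smooth_maps
    truth = gen(shape, ranges, rng)
    mask = np.ones(shape, dtype=bool)
    clean = np.asarray(
        twopool_signal(truth["S0"], truth["f"], truth["R2a"], truth["R2b"], echo_times)
    )
    noisy, sd = _add_noise(clean, mask, snr, rng, rician)
    return SyntheticTruth(
        truth, clean, noisy, mask, AcquisitionGrid({"echo_times": echo_times}), sd, snr, seed
    )


# -- SENSE/CAIPI phantom -------------------------------------------------------

def caipi_mask(spatial, Rz, z_shift, z_te_shift, n_echoes):
    """CAIPI sampling pattern: kz undersampled by Rz with a ky-dependent
    kz offset (z_shift per ky row), rotated by z_te_shift across echoes.
    Readout (kx) and ky are fully sampled (Ry = 1)."""
    nx, ny, nz = spatial
    if nz % Rz != 0:
        raise ValidationError(f"Rz={Rz} must divide the kz dimension {nz}")
    if not (0 <= z_shift < Rz and 0 <= z_te_shift < Rz):
        raise ValidationError("CAIPI shifts must satisfy 0 <= shift < Rz")
    ky = np.arange(ny)[:, None]
    kz = np.arange(nz)[None, :]
    mask = np.zeros((n_echoes, nx, ny, nz), dtype=bool)
    for e in range(n_echoes):
        offset = (ky * z_shift + e * z_te_shift) % Rz
        mask[e, :, :, :] = ((kz - offset) % Rz == 0)[None, :, :]
    return mask


def _synthetic_coils(spatial, n_coils, rng):
    """Smooth complex coil profiles, normalised so sum_c |C|^2 = 1."""
    nx, ny, nz = spatial
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz), indexing="ij"
    )
    C = np.empty((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cy, cz = 1.2 * np.cos(ang), 1.2 * np.sin(ang)
        d2 = x**2 * 0.3 + (y - cy) ** 2 + (z - cz) ** 2
        # localised profiles: broad coils cannot disambiguate Rz = 9 aliasing
        mag = np.exp(-d2 / 0.25) + 0.05
        pha = 0.7 * (np.cos(ang) * y - np.sin(ang) * z) + rng.uniform(0, 2 * np.pi)
        C[c] = mag * np.exp(1j * pha)
    norm = np.sqrt(np.sum(np.abs(C) ** 2, axis=0))
    return C / norm


def gen_phantom_recon(
    spatial=(6, 18, 36),
    n_coils=12,
    Rz=9,
    z_shift=3,
    z_te_shift=2,
    n_echoes=6,
    echo_times=None,
    noise_sd=0.0,
    seed=0,
) -> PhantomRecon:
    """Digital phantom with synthetic coils and CAIPI undersampling.

    The truth is a piecewise-constant complex object with per-echo
    mono-exponential magnitude decay; the default acquisition mirrors a
    6-echo GRE with TE1/dTE = 3/5 ms and Rz = 9 CAIPI (z-shift 3,
    z-TE-shift 2).
    """
    rng = np.random.default_rng(seed)
    if echo_times is None:
        echo_times = 3.0 + 5.0 * np.arange(n_echoes)  # TE1/dTE/TE6 = 3/5/28 ms
    echo_times = np.asarray(echo_times, dtype=float)
    ranges = {"S0": (0.5, 1.0), "R2star": (0.02, 0.08), "phase": (-2.0, 2.0)}
    maps = _piecewise_maps(spatial, ranges, rng)
    mag = np.asarray(monoexp_signal(maps["S0"], maps["R2star"], echo_times))
    # smoothly varying background phase plus per-echo evolution
    image = mag * np.exp(1j * maps["phase"][..., None])
    C = _synthetic_coils(spatial, n_coils, rng)
    mask_u = caipi_mask(spatial, Rz, z_shift, z_te_shift, n_echoes)
    k = np.asarray(sense_forward(image, C, mask_u))
    if noise_sd > 0:
        noise = noise_sd * (
            rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        )
        k = k + noise * mask_u[None]
    return PhantomRecon(
        image, C, mask_u, k, AcquisitionGrid({"echo_times": echo_times}), float(noise_sd), seed
    )


# -- conjugate-Gaussian toy ----------------------------------------------------

def gen_gaussian_toy(n_obs=100, theta_true=0.0, sigma=1.0, seed=0, n_voxels=1):
    """Observations ``y_i = theta + N(0, sigma^2)`` per voxel, plus the
    flat-prior closed-form posterior: mean = ybar, SD = sigma/sqrt(n)."""
    if n_obs < 2:
        raise ValidationError("n_obs must be >= 2")
    rng = np.random.default_rng(seed)
    y = theta_true + sigma * rng.standard_normal((n_voxels, n_obs))
    post_mean = y.mean(axis=1)
    post_sd = sigma / np.sqrt(n_obs)
    return {
        "y": y,
        "grid": AcquisitionGrid({"n_obs": [n_obs]}),
        "posterior_mean": post_mean,
        "posterior_sd": float(post_sd),
        "theta_true": float(theta_true),
        "sigma": float(sigma),
    }


# -- NLLS reference oracle -----------------------------------------------------

def nlls_oracle(model, signal, mask=None, grid=None, init=None, bounds=None, layout="volume"):
    """Independent bounded least-squares fit per masked voxel (trust region).

    The sequential voxel-wise reference the whole-volume solver is
    compared against.  Returns (ParameterMaps-style dict in volume
    layout, exit-code map: scipy status per voxel, < 0 on failure).
    """
    from .core import validate_inputs

    bundle = validate_inputs(signal, mask, grid=grid, layout=layout)
    bounds = bounds if bounds is not None else model.default_bounds
    names = tuple(model.param_names)
    sig = gather(bundle.signal, bundle.mask).reshape(int(bundle.mask.sum()), -1)
    V, m = sig.shape
    if m < len(names):
        raise ValidationError("need at least as many measurements as parameters")
    if init is None:
        init = model.default_init(bounds)
    lb = np.array([bounds[n][0] for n in names])
    ub = np.array([bounds[n][1] for n in names])
    x0_default = np.array([np.clip(float(np.mean(init[n])), lb[i], ub[i]) for i, n in enumerate(names)])

    est = np.empty((V, len(names)))
    status = np.empty(V, dtype=int)

    def resid_factory(y):
        def resid(x):
            params = {n: np.asarray(x[i]) for i, n in enumerate(names)}
            pred = np.asarray(model.evaluate(params, bundle.grid)).ravel()
            return pred - y

        return resid

    eps = 1e-12 * (ub - lb)
    for v in range(V):
        res = scipy.optimize.least_squares(
            resid_factory(sig[v]), np.clip(x0_default, lb + eps, ub - eps),
            bounds=(lb, ub), method="trf",
        )
        est[v] = res.x
        status[v] = res.status
    out = {
        n: scatter(est[:, i], bundle.mask, fill=np.nan) for i, n in enumerate(names)
    }
    return out, scatter(status, bundle.mask, fill=0)


# -- CG normal-equations baseline (lsqr stand-in) ------------------------------

def lsqr_baseline(k, C, mask_u, lam_tikhonov=0.0, max_iter=200, tol=1e-10):
    """Least-squares SENSE reconstruction via CG on the normal equations.

    Solves ``(E^H E + lam I) x = E^H k`` with ``E`` the SENSE/CAIPI
    encoding operator, i.e. minimises ``||k - E I||^2 + lam ||I||^2``.
    Deterministic given its inputs.
    """
    k = np.asarray(k, dtype=complex)
    n_echo = k.shape[1]
    spatial = k.shape[2:]
    shape = (*spatial, n_echo)
    n = int(np.prod(shape))

    def normal_op(x):
        I = x.reshape(shape)
        EhE = np.asarray(sense_adjoint(np.asarray(sense_forward(I, C, mask_u)), C, mask_u))
        return (EhE + lam_tikhonov * I).ravel()

    A = scipy.sparse.linalg.LinearOperator((n, n), matvec=normal_op, dtype=complex)
    b = np.asarray(sense_adjoint(k, C, mask_u)).ravel()
    x, info = scipy.sparse.linalg.cg(A, b, rtol=tol, maxiter=max_iter)
    if info < 0:
        raise RuntimeError(f"CG breakdown (info={info})")
    return x.reshape(shape)
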