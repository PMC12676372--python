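"""Regularisation terms for the whole-volume objective.

All terms are scalar-valued, nonnegative, and differentiable almost
everywhere (the subgradient of |x| at 0 is taken as 0), so they can be
added to the data loss with a user weight lambda and differentiated by
the autodiff engine.

* :func:`tv_spatial` — anisotropic total variation: mean absolute
  forward difference along the first 2 or 3 spatial axes; differences
  crossing the mask boundary are dropped (no smoothing across tissue/air
  edges).  The 2D variant is computed slice-wise over the third axis.
* :func:`tv_graph` — total variation over a vertex adjacency (e.g. a
  cortical surface mesh): the per-vertex sum of |theta_i - theta_j| over
  neighbours, so each undirected edge contributes twice.
* :func:`prior_penalty` — mean |theta - mu| / sigma against a per-voxel
  prior mean/SD map (e.g. ROI statistics from a high-SNR cohort).
* :func:`compose` — weighted sum of terms, including user-supplied
  custom callables that must return a finite scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .core import ValidationError

__all__ = [
    "GraphAdjacency",
    "PriorSpec",
    "compose",
    "prior_penalty",
    "tv_graph",
    "tv_spatial",
]


def _scalar(x):
    return x.data.item() if isinstance(x, ad.Tensor) else float(x)


# -- volumetric TV -------------------------------------------------------------

def tv_spatial(theta, mask=None, ndims: int = 3):
    """Anisotropic TV of a parameter volume: mean |forward difference|.

    ``theta`` has spatial dims first; ``ndims`` in {2, 3} selects the
    axes differenced (2 = slice-wise in-plane TV).  A difference is
    valid only if both endpoints are inside the mask.  Returns 0 when no
    valid difference exists (e.g. a single-voxel mask).
    """
    shape = theta.data.shape if isinstance(theta, ad.Tensor) else np.asarray(theta).shape
    if ndims not in (2, 3):
        raise ValidationError("ndims must be 2 or 3")
    if len(shape) < ndims:
        raise ValidationError(f"array rank {len(shape)} < ndims {ndims}")
    if mask is None:
        mask = np.ones(shape[: max(ndims, min(3, len(shape)))], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    total = None
    count = 0
    for ax in range(ndims):
        lo = [slice(None)] * len(shape)
        hi = [slice(None)] * len(shape)
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        mlo = [slice(None)] * mask.ndim
        mhi = [slice(None)] * mask.ndim
        mlo[ax] = slice(None, -1)
        mhi[ax] = slice(1, None)
        valid = mask[tuple(mlo)] & mask[tuple(mhi)]
        n_ax = int(valid.sum())
        if n_ax == 0:
            continue
        diff = ad.getitem(theta, tuple(hi)) - ad.getitem(theta, tuple(lo)) if isinstance(
            theta, ad.Tensor
        ) else np.asarray(theta)[tuple(hi)] - np.asarray(theta)[tuple(lo)]
        # keep only in-mask differences (valid may broadcast over trailing dims)
        if valid.ndim < (diff.data.ndim if isinstance(diff, ad.Tensor) else diff.ndim):
            trailing = (diff.data.shape if isinstance(diff, ad.Tensor) else diff.shape)[valid.ndim:]
            n_ax *= int(np.prod(trailing))
        sel = ad.getitem(diff, valid) if isinstance(diff, ad.Tensor) else diff[valid]
        s = ad.sum(ad.absolute(sel))
        total = s if total is None else total + s
        count += n_ax
    if total is None or count == 0:
        return 0.0
    return total / float(count)


# -- graph TV ------------------------------------------------------------------

@dataclass(frozen=True)
class GraphAdjacency:
    """Vertex adjacency as an edge list of unordered 0-based index pairs."""

    n_vertices: int
    edges: np.ndarray  # (n_edges, 2) int

    @classmethod
    def from_edges(cls, edges, n_vertices: int | None = None) -> "GraphAdjacency":
        edges = np.atleast_2d(np.asarray(edges, dtype=int))
        if edges.size == 0:
            edges = edges.reshape(0, 2)
        if edges.shape[1] != 2:
            raise ValidationError("edge list must have two columns")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValidationError("self-edges are not allowed")
        if np.any(edges < 0):
            raise ValidationError("vertex indices must be nonnegative (0-based)")
        n = int(edges.max()) + 1 if edges.size else 0
        if n_vertices is None:
            n_vertices = n
        elif n > n_vertices:
            raise ValidationError(f"edge refers to vertex {n - 1} >= n_vertices {n_vertices}")
        # canonicalise: sort endpoints, drop duplicate undirected edges
        e = np.sort(edges, axis=1)
        e = np.unique(e, axis=0)
        return cls(int(n_vertices), e)


def tv_graph(values, adjacency: GraphAdjacency):
    """Per-vertex graph TV: sum_i sum_{j in N(i)} |theta_i - theta_j|.

    Written as the per-vertex double sum, so each undirected edge
    contributes twice: the value equals 2 * sum_edges |theta_i - theta_j|.
    """
    n = values.data.shape[0] if isinstance(values, ad.Tensor) else np.asarray(values).shape[0]
    if n != adjacency.n_vertices:
        raise ValidationError(
            f"values length {n} != vertex count {adjacency.n_vertices}"
        )
    if adjacency.edges.shape[0] == 0:
        return 0.0
    i, j = adjacency.edges[:, 0], adjacency.edges[:, 1]
    diff = ad.getitem(values, i) - ad.getitem(values, j) if isinstance(
        values, ad.Tensor
    ) else np.asarray(values)[i] - np.asarray(values)[j]
    return 2.0 * ad.sum(ad.absolute(diff))


# -- prior penalty -------------------------------------------------------------

@dataclass
class PriorSpec:
    """Per-voxel (or per-vertex) prior mean and SD for one parameter."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)


def prior_penalty(theta, prior: PriorSpec, mask=None):
    """Mean over masked voxels of |theta - mu| / sigma."""
    shape = theta.data.shape if isinstance(theta, ad.Tensor) else np.asarray(theta).shape
    mu = np.broadcast_to(prior.mu, shape)
    sigma = np.broadcast_to(prior.sigma, shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any(sigma[mask] <= 0):
        raise ValidationError("prior sigma must be strictly positive inside the mask")
    dev = ad.absolute(theta - mu) / sigma
    sel = ad.getitem(dev, mask) if isinstance(dev, ad.Tensor) else dev[mask]
    return ad.sum(sel) / float(mask.sum())


# -- composition ---------------------------------------------------------------

def compose(terms):
    """Build a callable summing weighted regularisers.

    ``terms`` is a list of ``(fn, lam, param_names)``: ``fn`` takes one
    parameter array and returns a scalar; it is applied to each named
    parameter and scaled by ``lam >= 0``.  Terms with ``lam == 0``
    contribute exactly 0 (and are not evaluated).
    """
    for fn, lam, names in terms:
        if lam < 0:
            raise ValidationError(f"negative regularisation weight for {names}")

    def total(params: dict):
        acc = 0.0
        for fn, lam, names in terms:
            if lam == 0:
                continue
            if isinstance(names, str):
                names_seq = [names]
            else:
                names_seq = list(names)
            for name in names_seq:
                val = fn(params[name])
                sval = _scalar(val)
                if not np.isfinite(sval) or np.ndim(sval) != 0:
                    raise ValidationError(
                        f"regulariser for {name!r} returned a non-finite or non-scalar value"
                    )
                acc = acc + lam * val
        return acc

    return total
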