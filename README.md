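# qmrifit

Whole-volume parameter estimation for quantitative MRI: a gradient
solver that fits **every masked voxel in one objective** with reverse-mode
automatic differentiation, and a **vectorised MCMC sampler** for posterior
uncertainty — both driven by one pluggable forward-model contract — plus
TV/graph/prior regularisation and a SENSE/CAIPI image-reconstruction
application.  Everything runs on synthetic data generated in-package; no
downloads.

Who it is for: researchers fitting voxel-wise biophysical models
(relaxometry, multi-compartment GRE, diffusion-style kernels via the
plugin registry) who want volume-scale fitting with spatial
regularisation and calibrated uncertainty maps.

## The core idea

Voxel-wise NLLS solves, per voxel r,

```
argmin_θ ‖w (s_meas,r(φ) − s_r(φ, θ))‖₂²
```

sequentially over the volume.  `qmrifit` instead minimises one global
objective over the full masked volume,

```
argmin_θ ‖M W (S_meas(φ) − S(φ, θ))‖_{L1|L2} + Σ_k λ_k R_k(θ)
```

with Adam/SGDM/RMSProp on autodiff gradients taken in bound-preserving
(scaled-logit) space, where R_k are built-in 2D/3D total variation,
graph (mesh-vertex) TV, a prior penalty |θ − μ|/σ, or custom scalar
terms.  The companion sampler runs Metropolis–Hastings (independent
chains per voxel) or affine-invariant ensemble (stretch-move) MCMC with
a Gaussian likelihood and bound-truncated priors, vectorised across all
voxels yet bit-identical to a per-voxel sequential loop under the same
seed.  For reconstruction, the forward model is the SENSE/CAIPI
encoding operator `k = M_u · F(C · I)` (unitary FFT) and the unknown is
the complex multi-echo image.

## Worked example

Fit the mono-exponential R2* model to a noiseless synthetic 8×8×8,
12-echo GRE volume, then compare against the voxel-wise NLLS oracle:

```python
import numpy as np
from qmrifit import FitOptions, fit, gen_monoexp_volume, nlls_oracle
from qmrifit.models import get_model

data = gen_monoexp_volume(shape=(8, 8, 8), snr=1e9, seed=1)
model = get_model("monoexp_r2s")
res = fit(model, data.signal, data.mask, grid=data.grid,
          options=FitOptions(initial_learn_rate=0.01, iteration=4000,
                             loss_function="l2"))
for p in ("S0", "R2star"):
    rel = np.abs(res.final[p] - data.truth[p]) / data.truth[p]
    print(p, f"max relative error {100 * rel.max():.5f}%")
print("termination:", res.termination, "after", res.iterations, "iterations")
```

prints

```
S0 max relative error 0.00070%
R2star max relative error 0.00246%
termination: converged after 1618 iterations
```

i.e. the whole-volume fit recovers both maps to well below 0.1%,
stopping when the loss-slope criterion fires.  Posterior uncertainty for
the same model comes from the sampler:

```python
from qmrifit import McmcOptions, mh_sample, summarize

noisy = gen_monoexp_volume(shape=(4, 4, 4), snr=50, seed=2)
chains = mh_sample(model, noisy.signal, noisy.mask, grid=noisy.grid,
                   options=McmcOptions(iteration=25000, burnin=0.1, thinning=100,
                                       n_proposals=4, noise_sd=noisy.noise_sd, seed=0))
print("retained samples/voxel:", chains.n_retained)   # -> 900
s = summarize(chains, mask=noisy.mask)                # R2star mean/SD maps
```

With 4 chains × 25000 iterations, 10% burn-in and thinning 100 the
sampler retains exactly 900 posterior samples per voxel (50 walkers ×
2000 iterations under the ensemble algorithm retains the same 900).

A CLI mirrors the library: `qmrifit simulate | fit-askadam | fit-mcmc |
recon` (NIfTI in/out, HDF5 k-space containers, YAML/JSON grids).

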