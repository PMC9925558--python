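"""Ensemble-MCMC utilities: seeded sampling, MAP starts, split-chain Rhat.

Posteriors are sampled with an affine-invariant ensemble sampler (emcee).
Walkers are initialised in a small ball around a numerically located
posterior mode; post-warmup walker trajectories are pooled into the draw
store.  Each walker is treated as a chain for the split-Rhat diagnostic.
"""

from __future__ import annotations

import numpy as np
import emcee
from scipy import optimize


def map_start(log_prob, x0: np.ndarray, maxiter: int = 500) -> np.ndarray:
    """Posterior mode via L-BFGS-B with numerical gradients (best effort)."""
    def neg(x):
        v = float(np.asarray(log_prob(x[None, :]))[0])
        return -v if np.isfinite(v) else 1e12

    res = optimize.minimize(neg, x0, method="L-BFGS-B",
                            options={"maxiter": maxiter})
    return res.x if np.all(np.isfinite(res.x)) else x0


def split_rhat(chain: np.ndarray) -> np.ndarray:
    """Classic split-chain potential scale reduction factor.

    ``chain`` has shape (n_steps, n_chains, n_dim); each chain is split in
    half, and Rhat is computed per dimension from the between/within-sequence
    variances.
    """
    n, m, d = chain.shape
    half = n // 2
    seqs = np.concatenate([chain[:half], chain[half:2 * half]], axis=1)  # (half, 2m, d)
    means = seqs.mean(axis=0)                       # (2m, d)
    variances = seqs.var(axis=0, ddof=1)            # (2m, d)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def sample_posterior(log_prob_vec, x0: np.ndarray, seed: int,
                     n_walkers: int | None = None, warmup_steps: int = 400,
                     post_steps: int = 400, scatter: float = 0.05,
                     find_map: bool = True):
    """Run the ensemble sampler; returns (chain, rhat, n_draws).

    ``log_prob_vec`` maps an (n_walkers, ndim) array to log posterior values.
    ``chain`` has shape (post_steps, n_walkers, ndim); reproducible for a
    fixed seed.
    """
    x0 = np.asarray(x0, dtype=float)
    ndim = x0.size
    nw = n_walkers or max(2 * ndim + 2, 32)
    if nw % 2:
        nw += 1
    rng = np.random.default_rng(seed)
    center = map_start(log_prob_vec, x0) if find_map else x0

    p0 = center[None, :] + scatter * rng.standard_normal((nw, ndim))
    lp = np.asarray(log_prob_vec(p0))
    for _ in range(50):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        p0[bad] = center[None, :] + scatter * rng.standard_normal((int(bad.sum()), ndim))
        lp = np.asarray(log_prob_vec(p0))
    if not np.all(np.isfinite(np.asarray(log_prob_vec(p0)))):
        raise RuntimeError("could not initialise walkers at finite posterior density")

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob_vec, vectorize=True,
                                    moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    state = sampler.run_mcmc(state, warmup_steps)
    sampler.reset()
    sampler.run_mcmc(state, post_steps)
    chain = sampler.get_chain()  # (post_steps, nw, ndim)
    rhat = split_rhat(chain)
    return chain, rhat, chain.shape[0] * chain.shape[1]
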