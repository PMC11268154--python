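"""Adaptive random-walk Metropolis sampler.

Warm-up proceeds in two phases: coordinate-at-a-time Gaussian proposals
whose log-scales adapt toward a 44% acceptance rate (Robbins–Monro in
batches), then — once the chains have found the posterior bulk — a pooled
empirical covariance is estimated and joint multivariate-normal proposals
(scaled 2.38^2/k, the classic random-walk optimum) are mixed in, with the
global scale adapting toward 23% acceptance.  All adaptation freezes at the
end of warm-up, so the kept draws come from a valid fixed Markov kernel.
Chains update simultaneously as rows of a parameter matrix, keeping the
Python-level loop short.

Convergence is reported, not silently assumed: split-R-hat and bulk
effective sample size (via arviz) accompany every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

TARGET_ACCEPT_COORD = 0.44  # optimal for one-dimensional updates
TARGET_ACCEPT_JOINT = 0.23  # optimal for multivariate random walk
ADAPT_BATCH = 50

# convergence contract shared by all fits
RHAT_MAX = 1.01
ESS_MIN = 400.0


@dataclass
class McmcResult:
    draws: np.ndarray  # (n_chains, n_draws, k)
    accept_rate: np.ndarray  # per chain, per coordinate
    seed: int
    warnings: list[str] = field(default_factory=list)


def _coord_sweep(log_post, x, lp, log_scale, rng):
    """One Metropolis update of every coordinate in turn; returns acceptances."""
    n_chains, k = x.shape
    accepted = np.zeros((n_chains, k), dtype=bool)
    for j in range(k):
        prop = x.copy()
        prop[:, j] = x[:, j] + np.exp(log_scale[:, j]) * rng.standard_normal(n_chains)
        lp_prop = log_post(prop)
        with np.errstate(invalid="ignore"):
            acc = np.log(rng.random(n_chains)) < lp_prop - lp
        x[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        accepted[:, j] = acc
    return accepted


def _joint_step(log_post, x, lp, chol, log_lam, rng):
    n_chains, k = x.shape
    z = rng.standard_normal((n_chains, k))
    prop = x + np.exp(log_lam)[:, None] * (z @ chol.T)
    lp_prop = log_post(prop)
    with np.errstate(invalid="ignore"):
        acc = np.log(rng.random(n_chains)) < lp_prop - lp
    x[acc] = prop[acc]
    lp[acc] = lp_prop[acc]
    return acc


def run_chains(
    log_post: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    n_chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    init: np.ndarray | None = None,
) -> McmcResult:
    """Sample ``log_post`` over a box.

    Parameters
    ----------
    log_post : callable
        Maps a (n_chains, k) parameter matrix to a length-n_chains vector of
        log posterior densities; must return -inf outside the support.
    bounds : (k, 2) array
        Box constraints; also the support of the uniform initial draw.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]

    if init is None:
        x = rng.uniform(lo, hi, size=(n_chains, k))
    else:
        x = np.array(init, dtype=float)
    lp = log_post(x)
    for _ in range(100):  # re-draw chains that start on a zero-density point
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        x[bad] = rng.uniform(lo, hi, size=(int(bad.sum()), k))
        lp = log_post(x)

    log_scale = np.log(np.broadcast_to(0.1 * (hi - lo), (n_chains, k)).copy())
    log_lam = np.zeros(n_chains)
    chol: np.ndarray | None = None

    phase1 = n_warmup // 2
    buffer: list[np.ndarray] = []
    coord_hits = np.zeros((n_chains, k))
    joint_hits = np.zeros(n_chains)
    batch_no_c = 0
    batch_no_j = 0
    n_accept = np.zeros((n_chains, k))

    kept = np.empty((n_chains, n_draws, k))
    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        acc_c = _coord_sweep(log_post, x, lp, log_scale, rng)
        if chol is not None:
            acc_j = _joint_step(log_post, x, lp, chol, log_lam, rng)
            if warm:
                joint_hits += acc_j

        if warm:
            coord_hits += acc_c
            if it >= phase1 // 2:
                buffer.append(x.copy())
            if (it + 1) % ADAPT_BATCH == 0:
                batch_no_c += 1
                delta = min(0.25, 1.0 / np.sqrt(batch_no_c))
                log_scale += np.where(
                    coord_hits / ADAPT_BATCH > TARGET_ACCEPT_COORD, delta, -delta
                )
                coord_hits[:] = 0.0
                if chol is not None:
                    batch_no_j += 1
                    dj = min(0.25, 1.0 / np.sqrt(batch_no_j))
                    log_lam += np.where(
                        joint_hits / ADAPT_BATCH > TARGET_ACCEPT_JOINT, dj, -dj
                    )
                    joint_hits[:] = 0.0
            if it + 1 == phase1 and len(buffer) >= 10:
                pooled = np.concatenate(buffer, axis=0)
                cov = np.cov(pooled.T).reshape(k, k)
                cov += 1e-10 * np.eye(k) * np.trace(cov) / k + 1e-300 * np.eye(k)
                try:
                    chol = np.linalg.cholesky((2.38**2 / k) * cov)
                except np.linalg.LinAlgError:
                    chol = None
        else:
            n_accept += acc_c
            kept[:, it - n_warmup, :] = x

    return McmcResult(
        draws=kept,
        accept_rate=n_accept / max(n_draws, 1),
        seed=seed,
    )


def convergence_diagnostics(draws: np.ndarray, names: list[str]) -> tuple[dict, list[str]]:
    """Split-R-hat and bulk ESS per parameter from (chains, draws, k) draws."""
    import arviz as az

    diagnostics: dict[str, dict[str, float]] = {}
    warnings: list[str] = []
    for j, name in enumerate(names):
        arr = draws[:, :, j]
        rhat = float(az.rhat(arr))
        ess = float(az.ess(arr, method="bulk"))
        diagnostics[name] = {"rhat": rhat, "ess_bulk": ess}
        if not np.isfinite(rhat) or rhat > RHAT_MAX:
            warnings.append(f"split-R-hat {rhat:.4f} > {RHAT_MAX} for {name}")
        if ess < ESS_MIN:
            warnings.append(f"bulk ESS {ess:.0f} < {ESS_MIN:.0f} for {name}")
    return diagnostics, warnings
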