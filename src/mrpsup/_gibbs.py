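"""MCMC kernels for the multilevel models.

Two exact samplers over a shared design-matrix representation (fixed-effect
columns with fixed prior scales, plus varying-intercept blocks whose prior
scale is a per-block group standard deviation with a half-normal
hyperprior):

* cumulative ordinal probit -- Albert-Chib latent-variable Gibbs: truncated
  normal latents, jointly conjugate normal coefficient updates, slice-sampled
  group standard deviations, and Metropolis cutpoint updates on the
  (first cutpoint, log-spacings) transform with the latents integrated out,
  step size adapted during warmup;
* categorical logit -- Polya-Gamma augmented Gibbs: per non-reference
  category, omega ~ PG(1, psi_k - log sum_{j != k} exp(psi_j)) makes the
  conditional for that category's coefficients Gaussian.

Both kernels are plain functions of numpy arrays; model assembly, prediction
and diagnostics live in ``models``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri

from ._pg import pg_draws

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class GroupBlock:
    """Column block of one varying-intercept factor (or interaction)."""

    name: str
    idx: np.ndarray  # column indices into the design matrix


def trunc_norm(rng: np.random.Generator, mean, lo, hi) -> np.ndarray:
    """Vectorized N(mean, 1) truncated to (lo, hi) via inverse cdf."""
    a = ndtr(lo - mean)
    b = ndtr(hi - mean)
    u = a + rng.random(np.shape(mean)) * (b - a)
    z = mean + ndtri(np.clip(u, 1e-15, 1.0 - 1e-15))
    return np.clip(z, lo, hi)


def _slice_sample_logsd(x0: float, ssq: float, m: int, scale: float,
                        rng: np.random.Generator, width: float = 1.0) -> float:
    """Slice-sample log(sd) given m group effects with sum of squares ssq
    and a half-normal(scale) prior on sd."""

    def logp(x: float) -> float:
        v = math.exp(2.0 * x)
        return (1.0 - m) * x - ssq / (2.0 * v) - v / (2.0 * scale * scale)

    y = logp(x0) + math.log(rng.random() + 1e-300)
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(50):  # stepping out
        if logp(lo) < y:
            break
        lo -= width
    for _ in range(50):
        if logp(hi) < y:
            break
        hi += width
    while True:  # shrinkage
        x1 = lo + rng.random() * (hi - lo)
        if logp(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _update_group_sds(theta: np.ndarray, log_sds: np.ndarray,
                      blocks: list[GroupBlock], sd_scale: float,
                      rng: np.random.Generator) -> None:
    for j, blk in enumerate(blocks):
        ssq = float(np.sum(theta[blk.idx] ** 2))
        log_sds[j] = _slice_sample_logsd(log_sds[j], ssq, len(blk.idx),
                                         sd_scale, rng)


def _prior_precision(p: int, fixed_prec: np.ndarray, blocks: list[GroupBlock],
                     log_sds: np.ndarray) -> np.ndarray:
    d = fixed_prec.copy()
    for j, blk in enumerate(blocks):
        d[blk.idx] = math.exp(-2.0 * log_sds[j])
    return d


def _draw_coefficients(XtX: np.ndarray, Xtz: np.ndarray, d: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    a = XtX + np.diag(d)
    c, low = cho_factor(a, lower=False)
    mean = cho_solve((c, low), Xtz)
    # A = U' U with U upper; theta = mean + U^{-1} eps has covariance A^{-1}
    eps = rng.standard_normal(len(d))
    return mean + solve_triangular(c, eps, lower=False)


def _trunc_pos_normal(mean: float, sdev: float, rng: np.random.Generator) -> float:
    a = ndtr(-mean / sdev)
    u = a + rng.random() * (1.0 - a)
    return mean + sdev * float(ndtri(min(max(u, 1e-15), 1.0 - 1e-15)))


def _interweave_sds_gaussian(
    X: np.ndarray,
    theta: np.ndarray,
    log_sds: np.ndarray,
    blocks: list[GroupBlock],
    sd_scale: float,
    resid_target: np.ndarray,
    weights: np.ndarray | None,
    linpred: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Non-centered (ancillarity-sufficiency interweaving) group-sd update.

    Holding the standardized effects u/sd fixed, the conditional for each
    block's sd under a conditionally Gaussian likelihood is a positive
    truncated normal, which breaks the funnel between the sd and its
    effects.  ``resid_target`` is the Gaussian working response (latent z,
    or kappa/omega for the logistic augmentation with ``weights`` = omega);
    ``linpred`` is the current linear predictor consistent with theta.
    Returns the updated linear predictor.
    """
    w = weights if weights is not None else 1.0
    for j, blk in enumerate(blocks):
        sd = math.exp(log_sds[j])
        utilde = theta[blk.idx] / max(sd, 1e-12)
        v = X[:, blk.idx] @ utilde
        base = linpred - sd * v
        prec = float(np.sum(w * v * v)) + sd_scale**-2
        lin = float(np.sum(v * w * (resid_target - base)))
        new_sd = _trunc_pos_normal(lin / prec, prec**-0.5, rng)
        new_sd = max(new_sd, 1e-10)
        theta[blk.idx] = new_sd * utilde
        linpred = base + new_sd * v
        log_sds[j] = math.log(new_sd)
    return linpred


def _recenter_shift(
    sums: np.ndarray,
    sizes: np.ndarray,
    log_sds: np.ndarray,
    anchor_sum: float,
    anchor_n: int,
    anchor_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact Gibbs move along the likelihood-invariant shift directions.

    Every observation carries exactly one level of each varying-intercept
    block, so adding delta_b to all of block b's effects while shifting the
    anchor (cutpoints, or minus the intercept) by sum_b delta_b leaves the
    likelihood unchanged; the conditional for delta is Gaussian under the
    priors.  Sampling it removes the dominant slow-mixing direction of the
    blocked Gibbs sampler.  Returns delta per block.
    """
    nb = len(sizes)
    prec_b = sizes * np.exp(-2.0 * log_sds)
    prec_a = anchor_n / anchor_scale**2
    a = np.diag(prec_b) + prec_a
    b = sums * np.exp(-2.0 * log_sds) + anchor_sum / anchor_scale**2
    c, low = cho_factor(a, lower=False)
    mean = -cho_solve((c, low), b)
    return mean + solve_triangular(c, rng.standard_normal(nb), lower=False)


def _recenter_ordinal(theta, cuts, z, blocks, log_sds, cut_scale, rng):
    """Shift block effects by delta_b, cutpoints AND latents by sum(delta):
    the augmented-model likelihood is exactly invariant, so the conditional
    for delta is the prior-driven Gaussian of ``_recenter_shift``."""
    if not blocks:
        return cuts
    sums = np.array([theta[b.idx].sum() for b in blocks])
    sizes = np.array([len(b.idx) for b in blocks], dtype=float)
    delta = _recenter_shift(
        sums, sizes, log_sds, cuts.sum(), len(cuts), cut_scale, rng
    )
    for b, d in zip(blocks, delta):
        theta[b.idx] += d
    z += delta.sum()
    return cuts + delta.sum()


def _recenter_categorical(theta_k, blocks, log_sds_k, intercept_col,
                          intercept_scale, rng):
    if not blocks:
        return
    sums = np.array([theta_k[b.idx].sum() for b in blocks])
    sizes = np.array([len(b.idx) for b in blocks], dtype=float)
    # intercept shifts by -sum(delta); same Gaussian with anchor -alpha
    delta = _recenter_shift(
        sums, sizes, log_sds_k, -theta_k[intercept_col], 1, intercept_scale, rng
    )
    for b, d in zip(blocks, delta):
        theta_k[b.idx] += d
    theta_k[intercept_col] -= delta.sum()


# --------------------------------------------------------------------------
# ordinal probit
# --------------------------------------------------------------------------

def _cuts_to_gamma(cuts: np.ndarray) -> np.ndarray:
    if len(cuts) == 1:
        return cuts.copy()
    return np.concatenate([cuts[:1], np.log(np.diff(cuts))])


def _gamma_to_cuts(gamma: np.ndarray) -> np.ndarray:
    if len(gamma) == 1:
        return gamma.copy()
    return gamma[0] + np.concatenate([[0.0], np.cumsum(np.exp(gamma[1:]))])


def _ordinal_loglik(cuts: np.ndarray, eta: np.ndarray, y: np.ndarray,
                    k: int) -> float:
    cpad = np.concatenate([[-np.inf], cuts, [np.inf]])
    upper = cpad[y] - eta
    lower = cpad[y - 1] - eta
    # stable log(Phi(u) - Phi(l)); the pair never collapses because the
    # cutpoints are strictly increasing
    lu = log_ndtr(upper)
    ll = log_ndtr(lower)
    with np.errstate(divide="ignore"):
        out = lu + np.log1p(-np.clip(np.exp(ll - lu), 0.0, 1.0 - 1e-16))
    return float(out.sum())


def _cut_log_post(gamma: np.ndarray, eta: np.ndarray, y: np.ndarray, k: int,
                  cut_scale: float) -> float:
    cuts = _gamma_to_cuts(gamma)
    ll = _ordinal_loglik(cuts, eta, y, k)
    lp = float(np.sum(-0.5 * (cuts / cut_scale) ** 2
                      - math.log(cut_scale) - _LOG_SQRT_2PI))
    jac = float(np.sum(gamma[1:]))  # |d cuts / d gamma|
    return ll + lp + jac


def ordinal_gibbs_chain(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    blocks: list[GroupBlock],
    fixed_prec: np.ndarray,
    cut_scale: float,
    sd_scale: float,
    warmup: int,
    draws: int,
    seed: int,
    cut_steps: int = 3,
) -> dict[str, np.ndarray]:
    """One chain of the cumulative-probit Gibbs sampler.

    y must be integers in 1..k; returns post-warmup draws of coefficients,
    log group sds (as sds), cutpoints, and the cutpoint-move acceptance rate.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    XtX = X.T @ X
    theta = np.zeros(p)
    log_sds = np.full(len(blocks), math.log(0.5))
    freq = np.bincount(y - 1, minlength=k) + 0.5
    cum = np.cumsum(freq)[:-1] / freq.sum()
    cuts = ndtri(cum)
    cuts = np.maximum.accumulate(cuts)
    cuts += np.arange(k - 1) * 1e-3  # strictly increasing init
    gamma = _cuts_to_gamma(cuts)
    step = 0.05
    accepted = 0
    proposed = 0

    out_theta = np.empty((draws, p))
    out_sds = np.empty((draws, len(blocks))) if blocks else np.empty((draws, 0))
    out_cuts = np.empty((draws, k - 1))

    for it in range(warmup + draws):
        eta = X @ theta
        # cutpoints: Metropolis on the transformed scale, latents integrated out
        lp0 = _cut_log_post(gamma, eta, y, k, cut_scale)
        for _ in range(cut_steps):
            prop = gamma + step * rng.standard_normal(k - 1)
            lp1 = _cut_log_post(prop, eta, y, k, cut_scale)
            proposed += 1
            if math.log(rng.random() + 1e-300) < lp1 - lp0:
                gamma, lp0 = prop, lp1
                accepted += 1
            if it < warmup:
                rate = 1.0 if lp1 > lp0 else math.exp(min(0.0, lp1 - lp0))
                step *= math.exp(min(0.1, 10.0 / (it + 20)) * (rate - 0.3))
        cuts = _gamma_to_cuts(gamma)

        # latent responses
        cpad = np.concatenate([[-np.inf], cuts, [np.inf]])
        z = trunc_norm(rng, eta, cpad[y - 1], cpad[y])

        # coefficients jointly (fixed effects + all group effects)
        d = _prior_precision(p, fixed_prec, blocks, log_sds)
        theta = _draw_coefficients(XtX, X.T @ z, d, rng)

        # group standard deviations
        _update_group_sds(theta, log_sds, blocks, sd_scale, rng)

        # exact move along the likelihood-invariant shift directions
        cuts = _recenter_ordinal(theta, cuts, z, blocks, log_sds, cut_scale, rng)
        gamma = _cuts_to_gamma(cuts)

        # interweaved non-centered sd update (funnel breaker)
        _interweave_sds_gaussian(
            X, theta, log_sds, blocks, sd_scale, z, None, X @ theta, rng
        )

        if it >= warmup:
            j = it - warmup
            out_theta[j] = theta
            out_sds[j] = np.exp(log_sds)
            out_cuts[j] = cuts

    return {
        "theta": out_theta,
        "group_sd": out_sds,
        "cutpoints": out_cuts,
        "accept_rate": accepted / max(proposed, 1),
    }


# --------------------------------------------------------------------------
# categorical logit
# --------------------------------------------------------------------------

def categorical_gibbs_chain(
    X: np.ndarray,
    y: np.ndarray,
    n_cat: int,
    blocks: list[GroupBlock],
    fixed_prec: np.ndarray,
    sd_scale: float,
    warmup: int,
    draws: int,
    seed: int,
    intercept_col: int | None = 0,
) -> dict[str, np.ndarray]:
    """One chain of the Polya-Gamma Gibbs sampler for categorical logit.

    y must be integers in 0..n_cat-1; category 0 is the fixed reference with
    all coefficients zero.  Returns draws of theta (p x n_cat, reference
    column zero) and group sds per (block, category).
    """
    rng = np.random.default_rng(seed)
    pg_seeds = np.random.default_rng(seed + 1)
    n, p = X.shape
    theta = np.zeros((p, n_cat))
    n_free = n_cat - 1
    log_sds = np.full((len(blocks), n_free), math.log(0.5))
    psi = X @ theta

    out_theta = np.empty((draws, p, n_cat))
    out_sds = np.empty((draws, len(blocks), n_free))

    for it in range(warmup + draws):
        for kk in range(1, n_cat):
            others = [j for j in range(n_cat) if j != kk]
            m = logsumexp(psi[:, others], axis=1)
            eta = psi[:, kk] - m
            omega = pg_draws(eta, int(pg_seeds.integers(2**31 - 1)))
            kappa = (y == kk).astype(float) - 0.5
            d = _prior_precision(p, fixed_prec, blocks, log_sds[:, kk - 1])
            Xw = X * omega[:, None]
            a = X.T @ Xw + np.diag(d)
            b = X.T @ (kappa + omega * m)
            c, low = cho_factor(a, lower=False)
            mean = cho_solve((c, low), b)
            theta[:, kk] = mean + solve_triangular(
                c, rng.standard_normal(p), lower=False
            )
            psi[:, kk] = X @ theta[:, kk]
            _update_group_sds(theta[:, kk], log_sds[:, kk - 1], blocks,
                              sd_scale, rng)
            if intercept_col is not None:
                # psi-invariant recentring of blocks against the intercept
                _recenter_categorical(
                    theta[:, kk], blocks, log_sds[:, kk - 1], intercept_col,
                    fixed_prec[intercept_col] ** -0.5, rng,
                )
            # interweaved non-centered sd update using the PG augmentation
            with np.errstate(divide="ignore", invalid="ignore"):
                target = np.where(omega > 0, kappa / np.maximum(omega, 1e-300), 0.0)
            psi_tilde = _interweave_sds_gaussian(
                X, theta[:, kk], log_sds[:, kk - 1], blocks, sd_scale,
                target, omega, X @ theta[:, kk] - m, rng,
            )
            psi[:, kk] = psi_tilde + m

        if it >= warmup:
            j = it - warmup
            out_theta[j] = theta
            out_sds[j] = np.exp(log_sds)

    return {"theta": out_theta, "group_sd": out_sds}
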