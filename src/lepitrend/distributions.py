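"""Zero-inflated negative binomial and hurdle-gamma log densities.

Both response families use a log link for the conditional mean ``mu`` and an
intercept-only mixing probability ``pi``:

* ZINB: a point mass at zero with probability ``pi`` is mixed with a negative
  binomial with mean ``mu`` and shape ``phi`` (variance ``mu + mu**2/phi``),
  so zeros arise both structurally and from the count process.
* Hurdle gamma: exact zeros occur with probability ``pi``; strictly positive
  values follow a gamma with shape ``alpha`` and mean ``mu`` (rate
  ``alpha/mu``).

Alongside the public log densities, this module exposes the analytic
derivatives with respect to the linear predictor ``eta = log(mu)`` and the
auxiliary parameters, which the HMC sampler consumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln


def _validate_common(pi: float) -> None:
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"pi must lie in [0, 1], got {pi}")


def nb_logpmf(y, mu, phi):
    """Negative binomial log-pmf with mean ``mu`` and shape ``phi``.

    Parametrised so that ``var = mu + mu**2 / phi``; equivalent to
    ``scipy.stats.nbinom(n=phi, p=phi/(phi+mu))``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def zinb_logpmf(y, mu, phi, pi):
    """Log-pmf of the zero-inflated negative binomial.

    ``y = 0``: ``log(pi + (1-pi) * NB(0; mu, phi))``;
    ``y > 0``: ``log(1-pi) + log NB(y; mu, phi)``.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("y must be non-negative")
    if np.any(np.asarray(y) != np.floor(y)):
        raise ValueError("y must be integer-valued")
    _validate_common(pi)
    nb = nb_logpmf(y, mu, phi)
    if pi == 0.0:
        return nb
    yz = np.asarray(y) == 0
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    out = log_1mpi + nb
    if np.any(yz):
        zero_part = np.logaddexp(log_pi, log_1mpi + np.broadcast_to(nb, out.shape))
        out = np.where(yz, zero_part, out)
    return out


def hurdle_gamma_logpdf(y, mu, alpha, pi):
    """Log-density of the hurdle gamma.

    ``y = 0``: ``log(pi)``; ``y > 0``: ``log(1-pi)`` plus the gamma
    log-density with shape ``alpha`` and mean ``mu`` (rate ``alpha/mu``).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be >= 0")
    if np.any(mu <= 0) or alpha <= 0:
        raise ValueError("mu and alpha must be > 0")
    _validate_common(pi)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    rate = alpha / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = (
            log_1mpi
            + alpha * np.log(rate)
            - gammaln(alpha)
            + (alpha - 1.0) * np.log(y)
            - rate * y
        )
    return np.where(y == 0, log_pi, pos)


# ---------------------------------------------------------------------------
# Gradient kernels for the sampler.  All take the linear predictor eta and
# return per-observation log-likelihood contributions plus derivatives.
# ---------------------------------------------------------------------------


def zinb_loglik_grads(y, eta, phi, pi):
    """ZINB log-likelihood and gradients wrt (eta, phi, pi).

    Returns ``(ll, d_eta, d_phi, d_pi)`` where ``ll`` is the summed
    log-likelihood and ``d_eta`` is per-observation; ``d_phi`` and ``d_pi``
    are scalars (summed over observations).
    """
    y = np.asarray(y, dtype=float)
    mu = np.exp(eta)
    denom = phi + mu
    log_p0 = phi * (np.log(phi) - np.log(denom))  # log NB(0)
    yz = y == 0
    ypos = ~yz

    ll = 0.0
    d_eta = np.empty_like(mu)
    d_phi = 0.0
    d_pi = 0.0

    if np.any(ypos):
        yp = y[ypos]
        mup = mu[ypos]
        dp = denom[ypos]
        ll_pos = (
            gammaln(yp + phi)
            - gammaln(phi)
            - gammaln(yp + 1.0)
            + phi * (np.log(phi) - np.log(dp))
            + yp * (np.log(mup) - np.log(dp))
        )
        ll += np.sum(ll_pos) + np.count_nonzero(ypos) * np.log1p(-pi)
        d_eta[ypos] = yp - (yp + phi) * mup / dp
        d_phi += np.sum(
            digamma(yp + phi)
            - digamma(phi)
            + np.log(phi)
            - np.log(dp)
            + 1.0
            - (phi + yp) / dp
        )
        d_pi += -np.count_nonzero(ypos) / (1.0 - pi)

    if np.any(yz):
        p0 = np.exp(log_p0[yz])
        muz = mu[yz]
        dz = denom[yz]
        mix = pi + (1.0 - pi) * p0
        ll += np.sum(np.log(mix))
        # d p0 / d eta = -p0 * phi * mu / (phi + mu)
        d_eta[yz] = (1.0 - pi) * (-p0 * phi * muz / dz) / mix
        d_phi += np.sum(
            (1.0 - pi) * p0 * (np.log(phi) - np.log(dz) + 1.0 - phi / dz) / mix
        )
        d_pi += np.sum((1.0 - p0) / mix)

    return ll, d_eta, d_phi, d_pi


def hurdle_gamma_loglik_grads(y, eta, alpha, pi):
    """Hurdle-gamma log-likelihood and gradients wrt (eta, alpha, pi)."""
    y = np.asarray(y, dtype=float)
    mu = np.exp(eta)
    yz = y == 0
    ypos = ~yz
    n0 = int(np.count_nonzero(yz))
    n1 = int(np.count_nonzero(ypos))

    ll = 0.0
    d_eta = np.zeros_like(mu)
    d_alpha = 0.0
    d_pi = 0.0

    if n0:
        ll += n0 * np.log(pi) if pi > 0 else -np.inf
        d_pi += n0 / pi if pi > 0 else np.inf
    if n1:
        yp = y[ypos]
        mup = mu[ypos]
        ll += n1 * np.log1p(-pi)
        ll += np.sum(
            alpha * (np.log(alpha) - np.log(mup))
            - gammaln(alpha)
            + (alpha - 1.0) * np.log(yp)
            - alpha * yp / mup
        )
        d_eta[ypos] = alpha * (yp / mup - 1.0)
        d_alpha += np.sum(
            np.log(alpha) + 1.0 - np.log(mup) - digamma(alpha) + np.log(yp) - yp / mup
        )
        d_pi += -n1 / (1.0 - pi)
    return ll, d_eta, d_alpha, d_pi


class ZINBKernel:
    """Cached-response ZINB likelihood kernel for repeated gradient calls.

    Precomputes the grouping of observations by unique count value so the
    ``gammaln``/``digamma`` terms are evaluated once per unique count
    rather than once per observation.  Produces the same values as
    :func:`zinb_loglik_grads`.
    """

    def __init__(self, y):
        y = np.asarray(y, dtype=float)
        self.zero_mask = y == 0
        self.pos_idx = np.nonzero(~self.zero_mask)[0]
        self.yp = y[self.pos_idx]
        self.u, self.nu = np.unique(self.yp, return_counts=True)
        self.const_pos = -float(np.sum(gammaln(self.yp + 1.0)))
        self.n_pos = len(self.yp)
        self.n_zero = int(np.count_nonzero(self.zero_mask))

    def __call__(self, eta, phi, pi):
        mu = np.exp(eta)
        denom = phi + mu
        d_eta = np.zeros_like(mu)
        ll = 0.0
        d_phi = 0.0
        d_pi = 0.0
        log_phi = np.log(phi)

        if self.n_pos:
            idx = self.pos_idx
            yp = self.yp
            mup = mu[idx]
            dp = denom[idx]
            log_dp = np.log(dp)
            sum_log_dp = float(np.sum(log_dp))
            ll += (
                float(self.nu @ gammaln(self.u + phi))
                - self.n_pos * gammaln(phi)
                + self.const_pos
                + phi * (self.n_pos * log_phi - sum_log_dp)
                + float(yp @ eta[idx])          # y * log(mu), log mu == eta
                - float(yp @ log_dp)
                + self.n_pos * np.log1p(-pi)
            )
            d_eta[idx] = yp - (yp + phi) * mup / dp
            d_phi += (
                float(self.nu @ digamma(self.u + phi))
                - self.n_pos * digamma(phi)
                + self.n_pos * (log_phi + 1.0)
                - sum_log_dp
                - float(np.sum((phi + yp) / dp))
            )
            d_pi += -self.n_pos / (1.0 - pi) if pi < 1.0 else -np.inf

        if self.n_zero:
            zm = self.zero_mask
            muz = mu[zm]
            dz = denom[zm]
            log_dz = np.log(dz)
            p0 = np.exp(phi * (log_phi - log_dz))
            mix = pi + (1.0 - pi) * p0
            ll += float(np.sum(np.log(mix)))
            d_eta[zm] = (1.0 - pi) * (-p0 * phi * muz / dz) / mix
            d_phi += float(
                np.sum((1.0 - pi) * p0 * (log_phi - log_dz + 1.0 - phi / dz) / mix)
            )
            d_pi += float(np.sum((1.0 - p0) / mix))

        return ll, d_eta, d_phi, d_pi


class HurdleGammaKernel:
    """Cached-response hurdle-gamma likelihood kernel (see ZINBKernel)."""

    def __init__(self, y):
        y = np.asarray(y, dtype=float)
        self.zero_mask = y == 0
        self.pos_idx = np.nonzero(~self.zero_mask)[0]
        self.yp = y[self.pos_idx]
        self.sum_log_yp = float(np.sum(np.log(self.yp))) if len(self.yp) else 0.0
        self.n_pos = len(self.yp)
        self.n_zero = int(np.count_nonzero(self.zero_mask))

    def __call__(self, eta, alpha, pi):
        mu = np.exp(eta)
        d_eta = np.zeros_like(mu)
        ll = 0.0
        d_alpha = 0.0
        d_pi = 0.0
        if self.n_zero:
            ll += self.n_zero * np.log(pi) if pi > 0 else -np.inf
            d_pi += self.n_zero / pi if pi > 0 else np.inf
        if self.n_pos:
            idx = self.pos_idx
            yp = self.yp
            mup = mu[idx]
            eta_p = eta[idx]
            y_over_mu = yp / mup
            sum_eta = float(np.sum(eta_p))
            ll += (
                self.n_pos * np.log1p(-pi)
                + alpha * (self.n_pos * np.log(alpha) - sum_eta)
                - self.n_pos * gammaln(alpha)
                + (alpha - 1.0) * self.sum_log_yp
                - alpha * float(np.sum(y_over_mu))
            )
            d_eta[idx] = alpha * (y_over_mu - 1.0)
            d_alpha += (
                self.n_pos * (np.log(alpha) + 1.0 - digamma(alpha))
                - sum_eta
                + self.sum_log_yp
                - float(np.sum(y_over_mu))
            )
            d_pi += -self.n_pos / (1.0 - pi)
        return ll, d_eta, d_alpha, d_pi


def zinb_mean_var(mu, phi, pi):
    """Marginal mean and variance of the ZINB: ``(1-pi)mu`` and
    ``(1-pi)mu(1 + mu/phi + pi*mu)``."""
    mean = (1.0 - pi) * mu
    var = (1.0 - pi) * mu * (1.0 + mu / phi + pi * mu)
    return mean, var
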