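"""Gaussian mixture deconvolution of log10 marker intensities.

PCNA staining separates into negative / diffuse / punctate populations
(3 components); pH3 into negative / positive (2 components).  The
mixture is fit on log10 intensity by expectation-maximization with
quantile-based initialization and seeded-jitter restarts; component
weights are the reported population "areas".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MixtureFitError(RuntimeError):
    pass


@dataclass
class MixtureFit:
    k: int
    means: np.ndarray       # log10 a.u., strictly increasing
    sigmas: np.ndarray
    weights: np.ndarray     # sum to 1
    boundaries: np.ndarray  # posterior-equality points between neighbors, log10
    log_likelihood: float
    n_iter: int
    degenerate: bool = False  # a component collapsed or merged
    ll_trace: np.ndarray | None = None  # per-iteration log-likelihood (best restart)

    def predict_component(self, values: np.ndarray) -> np.ndarray:
        """Hard component assignment of raw (linear) intensities."""
        x = np.log10(np.asarray(values, dtype=float))
        resp = self._responsibilities(x)
        return np.argmax(resp, axis=1)

    def _responsibilities(self, x: np.ndarray) -> np.ndarray:
        logp = (
            np.log(self.weights)[None, :]
            - 0.5 * ((x[:, None] - self.means[None, :]) / self.sigmas[None, :]) ** 2
            - np.log(self.sigmas)[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _em(x, mu, sigma, w, tol, max_iter):
    n = len(x)
    trace = []
    for it in range(max_iter):
        logp = (
            np.log(w)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma)[None, :] - 0.5 * np.log(2 * np.pi)
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, 1e-10))
        trace.append(ll)
        if it > 0 and ll - trace[-2] < tol:
            break
    return mu, sigma, w, trace[-1], len(trace), np.asarray(trace)


def _boundary(m1, s1, w1, m2, s2, w2):
    """log10 point where the two weighted component densities are equal."""
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = (m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2)
         + np.log(w2 / s2) - np.log(w1 / s1))
    if abs(a) < 1e-14:
        return -c / b if b != 0 else 0.5 * (m1 + m2)
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    return float(inside[0]) if len(inside) else 0.5 * (m1 + m2)


def fit_log_mixture(
    values: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """EM fit of a k-component Gaussian mixture on log10 intensities.

    Components are reported in increasing order of mean.  Initialization
    places means at the (2i+1)/(2k) quantiles; restarts jitter those
    means with seeded Gaussian noise and the best log-likelihood wins.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("intensities must be positive for a log fit")
    x = np.log10(v)
    if len(x) < 10 * k:
        raise MixtureFitError("too few events for a mixture fit")

    rng = np.random.default_rng(seed)
    q = np.quantile(x, [(2 * i + 1) / (2 * k) for i in range(k)])
    spread = max(x.std(), 1e-3)
    best = None
    for r in range(n_restarts):
        mu0 = q if r == 0 else q + rng.normal(0.0, 0.3 * spread, k)
        sigma0 = np.full(k, spread / k)
        w0 = np.full(k, 1.0 / k)
        try:
            mu, sigma, w, ll, n_it, trace = _em(x, mu0.copy(), sigma0, w0, tol, max_iter)
        except FloatingPointError:
            continue
        if best is None or ll > best[3]:
            best = (mu, sigma, w, ll, n_it, trace)
    if best is None:
        raise MixtureFitError("EM failed on every restart")
    mu, sigma, w, ll, n_it, trace = best
    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    # a component is spurious if nearly empty or if two means sit closer
    # than two standard deviations (one population split in half)
    degenerate = bool(
        np.any(w < 0.02)
        or np.any(np.diff(mu) < 2.0 * np.maximum(sigma[:-1], sigma[1:]))
    )
    bounds = np.array([
        _boundary(mu[i], sigma[i], w[i], mu[i + 1], sigma[i + 1], w[i + 1])
        for i in range(k - 1)
    ])
    return MixtureFit(
        k=k, means=mu, sigmas=sigma, weights=w, boundaries=bounds,
        log_likelihood=ll, n_iter=n_it, degenerate=degenerate, ll_trace=trace,
    )
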