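"""Log-space hypergeometric kernels used by the count distributions.

All series here have strictly positive terms (the Kummer transform is applied
before calling these), so they can be summed with logsumexp without
cancellation.  Pochhammer symbols are RISING factorials throughout,
(x)_n = x (x+1) ... (x+n-1) = Gamma(x+n)/Gamma(x).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["log_rising", "log_hyp1f1_pos", "telegraph_log_pmf_grid"]


def log_rising(x, n):
    """log of the rising factorial (x)_n for x > 0, integer n >= 0."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    return gammaln(x + n) - gammaln(x)


def _k_upper(a_max: float, b_min: float, x: float) -> int:
    # term ratio t_{k+1}/t_k = (a+k) x / ((b+k)(k+1)); the peak index solves
    # (a+k) x = (b+k)(k+1); bound it by the larger root of k^2 - x k - a x = 0
    peak = 0.5 * (x + np.sqrt(x * x + 4.0 * a_max * x))
    return int(peak + 10.0 * np.sqrt(peak + 4.0) + 30.0)


def log_hyp1f1_pos(a, b, x):
    """log 1F1(a, b, x) for a > 0, b > 0 and x >= 0 (broadcasting).

    The series sum_k (a)_k x^k / ((b)_k k!) has positive terms for x >= 0,
    so the sum is done in log space.  The number of terms is chosen from the
    position of the largest term and extended if the tail has not decayed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log_hyp1f1_pos requires x >= 0; apply the Kummer transform first")
    shape = np.broadcast_shapes(a.shape, b.shape, x.shape)
    a, b, x = (np.broadcast_to(v, shape) for v in (a, b, x))
    xmax = float(x.max()) if x.size else 0.0
    K = _k_upper(float(a.max()) if a.size else 1.0, float(b.min()) if b.size else 1.0, xmax)
    while True:
        k = np.arange(K + 1, dtype=float)
        # shape (..., K+1)
        logt = (
            log_rising(a[..., None], k)
            - log_rising(b[..., None], k)
            + k * np.log(np.where(x[..., None] > 0, x[..., None], 1.0))
            - gammaln(k + 1.0)
        )
        logt = np.where((x[..., None] == 0) & (k > 0), -np.inf, logt)
        out = logsumexp(logt, axis=-1)
        # tail check: last term negligible relative to the sum
        if np.all(logt[..., -1] < out - 36.0):
            return out
        K *= 2


def telegraph_log_pmf_grid(rho, sigma_on: float, sigma_off: float, n_max: int):
    """Log pmf of the telegraph (Beta-Poisson) model on n = 0..n_max.

    ``rho`` may be an array (one transcription rate per quadrature node or
    per cell), in which case the result has shape ``(len(rho), n_max + 1)``.

    Uses P(n) = rho^n/n! (s_on)_n/(N)_n e^{-rho} 1F1(s_off, N + n, rho),
    the Kummer-transformed form with an everywhere-positive series.  When the
    series would need very many terms (large sigma_off), the Beta-Poisson
    mixture is integrated by Gauss-Jacobi quadrature instead.
    """
    rho = np.asarray(rho, dtype=float)
    scalar = rho.ndim == 0
    rho = np.atleast_1d(rho)
    if np.any(rho < 0) or sigma_on <= 0 or sigma_off <= 0:
        raise ValueError("telegraph rates must satisfy rho >= 0, sigma_on > 0, sigma_off > 0")
    xmax = float(rho.max()) if rho.size else 0.0
    if _k_upper(sigma_off, sigma_on + sigma_off, xmax) > 700:
        # long series: try the quadrature route (it fails for huge Beta
        # shapes, where the series below is the robust one)
        with np.errstate(all="ignore"):
            out = telegraph_log_pmf_jacobi_multi(rho, sigma_on, sigma_off, n_max)
        if np.all(np.isfinite(out[:, :1])):
            return out[0] if scalar else out
    n = np.arange(n_max + 1, dtype=float)
    nsig = sigma_on + sigma_off
    logrho = np.log(np.where(rho > 0, rho, 1.0))
    pref = (
        n[None, :] * logrho[:, None]
        - gammaln(n + 1.0)[None, :]
        + (log_rising(sigma_on, n) - log_rising(nsig, n))[None, :]
        - rho[:, None]
    )
    pref = np.where((rho[:, None] == 0) & (n[None, :] > 0), -np.inf, pref)
    logf = log_hyp1f1_pos(sigma_off, nsig + n[None, :], rho[:, None])
    out = pref + logf
    # zero-rate rows are an exact point mass at n = 0
    out[rho == 0, 0] = 0.0
    if not np.all(np.isfinite(out[:, :1])):
        raise FloatingPointError("telegraph pmf evaluation failed")
    return out[0] if scalar else out


def beta_measure_rule(n_nodes: int, a: float, b: float):
    """Gauss-Jacobi rule normalized against the Beta(a, b) probability measure.

    Returns nodes p in (0, 1) and weights summing to 1 such that
    sum_i w_i f(p_i) ~= E[f(P)] for P ~ Beta(a, b).  Built by Golub-Welsch on
    the Jacobi recurrence coefficients; normalizing against the Beta measure
    cancels the total-mass constant, so this stays finite for arbitrarily
    large shape parameters (where scipy's roots_jacobi overflows).
    """
    from scipy.linalg import eigh_tridiagonal

    alpha, beta_ = b - 1.0, a - 1.0  # weight (1-x)^alpha (1+x)^beta on [-1, 1]
    apb = alpha + beta_
    k = np.arange(n_nodes, dtype=float)
    diag = np.empty(n_nodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = (beta_**2 - alpha**2) / ((2 * k + apb) * (2 * k + apb + 2.0))
    if abs(apb) < 1e-300:
        diag[0] = (beta_ - alpha) / (apb + 2.0)
    kk = k[1:]
    num = 4.0 * kk * (kk + alpha) * (kk + beta_) * (kk + apb)
    den = (2 * kk + apb) ** 2 * ((2 * kk + apb) ** 2 - 1.0)
    off = np.sqrt(num / den)
    x, v = eigh_tridiagonal(diag, off)
    return 0.5 * (x + 1.0), v[0, :] ** 2


def telegraph_log_pmf_jacobi_multi(rho, sigma_on: float, sigma_off: float,
                                   n_max: int, n_nodes: int = 100):
    """Beta-Poisson mixture by Gauss-Jacobi quadrature, vectorized over rho.

    Integrates Poisson(n; rho x) against the Beta(sigma_on, sigma_off)
    measure exactly for polynomial factors; serves both as an independent
    route to the series evaluation and as the fast path when the series is
    long.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    p, w = beta_measure_rule(n_nodes, sigma_on, sigma_off)
    with np.errstate(divide="ignore"):
        logw = np.log(np.clip(w, 1e-320, None))
    n = np.arange(n_max + 1, dtype=float)
    lam = rho[:, None] * p[None, :]  # (R, J)
    loglam = np.log(np.where(lam > 0, lam, 1.0))
    # (R, J, N)
    logpois = (n[None, None, :] * loglam[:, :, None] - lam[:, :, None]
               - gammaln(n + 1.0)[None, None, :])
    logpois = np.where((lam[:, :, None] == 0) & (n[None, None, :] > 0), -np.inf, logpois)
    return logsumexp(logpois + logw[None, :, None], axis=1)


def telegraph_log_pmf_jacobi(rho: float, sigma_on: float, sigma_off: float,
                             n_max: int, n_nodes: int = 200):
    """Scalar-rho convenience wrapper around the Gauss-Jacobi route."""
    return telegraph_log_pmf_jacobi_multi(rho, sigma_on, sigma_off, n_max, n_nodes)[0]
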