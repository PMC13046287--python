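"""Steady-state count distributions of the telegraph, NB and Poisson models.

The telegraph model describes a gene switching between an active state
(transcribing at rate ``rho``) and an inactive state, with activation rate
``sigma_on`` and inactivation rate ``sigma_off``; all rates are normalized by
the mRNA degradation rate.  Its steady-state count distribution is the
Beta-Poisson compound

    n ~ Poisson(rho * x),   x ~ Beta(sigma_on, sigma_off),

whose pmf has a closed form in terms of the Kummer confluent hypergeometric
function 1F1 with rising-factorial Pochhammer symbols.  The "effective NB"
is the negative binomial whose first two moments match the telegraph model
exactly; it converges to the telegraph distribution at rate O(1/N_sigma) as
N_sigma = sigma_on + sigma_off grows, and also in the classical bursting
limit sigma_off -> inf at fixed rho/sigma_off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._hyp import telegraph_log_pmf_grid, telegraph_log_pmf_jacobi

__all__ = [
    "TelegraphParams",
    "NBParams",
    "PoissonParams",
    "PMFVector",
    "telegraph_pmf",
    "telegraph_log_pmf",
    "telegraph_moments",
    "effective_nb_params",
    "nb_pmf",
    "poisson_pmf",
    "sample_telegraph",
    "kl_divergence",
    "entropy",
    "DEFAULT_TAIL_TOL",
]

DEFAULT_TAIL_TOL = 1e-10


@dataclass(frozen=True)
class TelegraphParams:
    """Telegraph-model rates (rho, sigma_on, sigma_off), degradation-normalized.

    ``rho`` may be zero (silent gene); the switching rates must be positive.
    """

    rho: float
    sigma_on: float
    sigma_off: float

    def __post_init__(self):
        for name in ("rho", "sigma_on", "sigma_off"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.sigma_on <= 0 or self.sigma_off <= 0:
            raise ValueError("sigma_on and sigma_off must be > 0")

    @property
    def n_sigma(self) -> float:
        """Sum of switching rates relative to mRNA degradation."""
        return self.sigma_on + self.sigma_off

    @property
    def f_on(self) -> float:
        """Fraction of time spent in the active state."""
        return self.sigma_on / (self.sigma_on + self.sigma_off)

    @classmethod
    def from_fon_nsigma(cls, rho: float, f_on: float, n_sigma: float) -> "TelegraphParams":
        if not 0.0 < f_on < 1.0:
            raise ValueError(f"f_on must lie in (0, 1), got {f_on}")
        if n_sigma <= 0:
            raise ValueError(f"n_sigma must be > 0, got {n_sigma}")
        return cls(rho=rho, sigma_on=f_on * n_sigma, sigma_off=(1.0 - f_on) * n_sigma)


@dataclass(frozen=True)
class NBParams:
    """Negative binomial NB(r, p): mean r(1-p)/p, variance r(1-p)/p^2."""

    r: float
    p: float

    def __post_init__(self):
        if not (self.r > 0 and math.isfinite(self.r)):
            raise ValueError(f"r must be positive and finite, got {self.r}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")

    @property
    def mean(self) -> float:
        return self.r * (1.0 - self.p) / self.p

    @property
    def variance(self) -> float:
        return self.r * (1.0 - self.p) / self.p**2


@dataclass(frozen=True)
class PoissonParams:
    lam: float

    def __post_init__(self):
        if not (self.lam >= 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be >= 0 and finite, got {self.lam}")


class PMFVector:
    """Truncated pmf over counts n = 0..n_max with tracked tail mass."""

    __slots__ = ("probs", "tail_mass")

    def __init__(self, probs, tail_tol: float = DEFAULT_TAIL_TOL, check: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("probs must be a nonempty 1-D array")
        if check:
            if np.any(probs < 0) or not np.all(np.isfinite(probs)):
                raise ValueError("pmf entries must be finite and nonnegative")
            s = probs.sum()
            if s > 1.0 + 1e-9:
                raise ValueError(f"pmf sums to {s} > 1")
        self.probs = probs
        self.tail_mass = max(0.0, 1.0 - float(probs.sum()))

    @property
    def n_max(self) -> int:
        return self.probs.size - 1

    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)

    def variance(self) -> float:
        n = np.arange(self.probs.size)
        m = self.mean()
        return float((n - m) ** 2 @ self.probs)

    def truncate_to_mass(self, mass: float = 1.0 - DEFAULT_TAIL_TOL) -> "PMFVector":
        """Shortest prefix whose cumulative probability exceeds ``mass``."""
        c = np.cumsum(self.probs)
        idx = int(np.searchsorted(c, mass)) + 1
        return PMFVector(self.probs[:idx], check=False)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"n": np.arange(self.probs.size), "probability": self.probs}).to_csv(
            path, sep="\t", index=False
        )

    def __len__(self) -> int:
        return self.probs.size

    def __repr__(self) -> str:
        return f"PMFVector(n_max={self.n_max}, tail_mass={self.tail_mass:.3g})"


def _auto_nmax(mean: float, var: float, n_max: int | None) -> int:
    if n_max is not None:
        if n_max < 0:
            raise ValueError("n_max must be >= 0")
        return n_max
    return int(math.ceil(mean + 10.0 * math.sqrt(max(var, 1e-12)))) + 5


def _extend_until_normalized(logpmf_fn, n_max: int, tail_tol: float) -> np.ndarray:
    """Evaluate a log-pmf callable, growing n_max until tail mass < tail_tol."""
    for _ in range(40):
        probs = np.exp(logpmf_fn(n_max))
        if 1.0 - probs.sum() < tail_tol:
            return probs
        n_max = int(n_max * 1.6) + 20
    raise RuntimeError("pmf failed to normalize within the truncation budget")


def telegraph_log_pmf(params: TelegraphParams, n_max: int) -> np.ndarray:
    """Log pmf of the telegraph model on n = 0..n_max (series evaluation,
    Gauss-Jacobi quadrature of the Beta-Poisson mixture as fallback)."""
    try:
        return telegraph_log_pmf_grid(params.rho, params.sigma_on, params.sigma_off, n_max)
    except FloatingPointError:
        return telegraph_log_pmf_jacobi(params.rho, params.sigma_on, params.sigma_off, n_max)


def telegraph_pmf(params: TelegraphParams, n_max: int | None = None,
                  tail_tol: float = DEFAULT_TAIL_TOL) -> PMFVector:
    """Steady-state telegraph-model pmf.

    With ``n_max=None`` the truncation starts at mean + 10 sd and is extended
    until the tail mass drops below ``tail_tol``.
    """
    m, v = telegraph_moments(params)
    nm = _auto_nmax(m, v, n_max)
    if n_max is not None:
        return PMFVector(np.exp(telegraph_log_pmf(params, nm)), check=False)
    probs = _extend_until_normalized(lambda k: telegraph_log_pmf(params, k), nm, tail_tol)
    return PMFVector(probs, check=False)


def telegraph_moments(params: TelegraphParams) -> tuple[float, float]:
    """Exact mean and variance of the telegraph model."""
    rho, son, soff = params.rho, params.sigma_on, params.sigma_off
    nsig = son + soff
    mean = rho * son / nsig
    var = rho * son * (nsig * (nsig + 1.0) + rho * soff) / (nsig**2 * (nsig + 1.0))
    return mean, var


def effective_nb_params(params: TelegraphParams) -> NBParams:
    """NB(r_e, p_e) with the same first two moments as the telegraph model:

        r_e = sigma_on (N + 1) / sigma_off,
        p_e = N (N + 1) / (N (N + 1) + rho sigma_off),   N = N_sigma.
    """
    rho, son, soff = params.rho, params.sigma_on, params.sigma_off
    if rho == 0:
        raise ValueError("rho = 0: degenerate distribution has no NB moment match")
    nsig = son + soff
    re = son * (nsig + 1.0) / soff
    pe = nsig * (nsig + 1.0) / (nsig * (nsig + 1.0) + rho * soff)
    return NBParams(r=re, p=pe)


def _nb_log_pmf(params: NBParams, n_max: int) -> np.ndarray:
    n = np.arange(n_max + 1)
    return stats.nbinom.logpmf(n, params.r, params.p)


def nb_pmf(params: NBParams, n_max: int | None = None,
           tail_tol: float = DEFAULT_TAIL_TOL) -> PMFVector:
    nm = _auto_nmax(params.mean, params.variance, n_max)
    if n_max is not None:
        return PMFVector(np.exp(_nb_log_pmf(params, nm)), check=False)
    probs = _extend_until_normalized(lambda k: _nb_log_pmf(params, k), nm, tail_tol)
    return PMFVector(probs, check=False)


def poisson_pmf(params: PoissonParams, n_max: int | None = None,
                tail_tol: float = DEFAULT_TAIL_TOL) -> PMFVector:
    nm = _auto_nmax(params.lam, max(params.lam, 1e-12), n_max)
    logf = lambda k: stats.poisson.logpmf(np.arange(k + 1), params.lam)
    if n_max is not None:
        return PMFVector(np.exp(logf(nm)), check=False)
    return PMFVector(_extend_until_normalized(logf, nm, tail_tol), check=False)


def sample_telegraph(params: TelegraphParams, n_samples: int,
                     seed: int | np.random.Generator) -> np.ndarray:
    """I.i.d. telegraph counts via the Beta-Poisson representation."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.beta(params.sigma_on, params.sigma_off, size=n_samples)
    return rng.poisson(params.rho * x)


def kl_divergence(p: PMFVector, q: PMFVector) -> float:
    """Kullback-Leibler divergence sum_n P(n) ln[P(n)/Q(n)] on common support."""
    if len(p) != len(q):
        raise ValueError(
            f"support mismatch: len(P) = {len(p)} vs len(Q) = {len(q)}; "
            "truncate both pmfs to a common n_max first"
        )
    mask = p.probs > 0
    if np.any(q.probs[mask] <= 0):
        raise ValueError("Q must be positive wherever P is positive")
    pp = p.probs[mask]
    return float(np.sum(pp * (np.log(pp) - np.log(q.probs[mask]))))


def entropy(p: PMFVector) -> float:
    """Shannon entropy -sum_n P(n) ln P(n) of the truncated pmf."""
    pp = p.probs[p.probs > 0]
    return float(-np.sum(pp * np.log(pp)))
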