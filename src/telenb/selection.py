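"""aeBIC model selection among telegraph, NB and Poisson count models.

For a known ground-truth pmf G (here the telegraph model, optionally
downsampled by a capture model), the approximate expected Bayesian
information criterion

    aeBIC(M, nc) = |M| ln nc + 2 nc eps_c(M, G),

with eps_c the cross entropy between the fitted model M and G, is an upper
bound on — and in practice an excellent estimator of — the BIC averaged over
infinitely many datasets of nc cells sampled from G.  It lets a unique best
model be attached to every parameter point without simulating data, which is
what makes dense (N_sigma, f_on) phase diagrams affordable.

Candidates can be "standard" (fitted as if all transcripts were observed) or
"corrected" (their pmfs are integrated over the known capture model before
fitting), mirroring how real pipelines do or do not model technical noise.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .capture import (
    CaptureModel,
    _tele_beta_log_quad,
    observed_moments_telegraph_beta,
    observed_pmf_nb_beta,
    observed_pmf_poisson_beta,
)
from .distributions import (
    NBParams,
    PMFVector,
    PoissonParams,
    TelegraphParams,
    entropy,
    nb_pmf,
    poisson_pmf,
    telegraph_log_pmf,
    telegraph_moments,
    telegraph_pmf,
)

_log = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "CandidateModel",
    "FitResult",
    "PhaseGrid",
    "PhaseDiagram",
    "EntropyScan",
    "cross_entropy",
    "fit_model_to_pmf",
    "aebic",
    "bic",
    "expected_bic_mc",
    "select_best",
    "cross_entropy_scan",
    "phase_scan",
]

MODEL_KINDS = ("telegraph", "nb", "poisson")
_N_PARAMS = {"telegraph": 3, "nb": 2, "poisson": 1}


@dataclass(frozen=True)
class CandidateModel:
    """A candidate count model: kind plus whether its pmf is integrated over
    the (known) capture model.  Capture parameters are treated as known and
    do not count toward the BIC penalty."""

    kind: str
    corrected: bool = False

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.kind]


@dataclass
class FitResult:
    model: CandidateModel
    theta: tuple
    cross_entropy: float  # eps_c for population fits, or mean neg-log-lik for samples
    criterion: float | None = None
    method: str = "mle"
    converged: bool = True
    log_likelihood: float | None = None  # total, for sample-based fits


def cross_entropy(model_pmf: PMFVector, truth_pmf: PMFVector) -> float:
    """eps_c = -sum_n P_G(n) ln P_M(n) over the (common) truncated support.

    Returns +inf if the model assigns zero probability to a supported count.
    """
    if len(model_pmf) != len(truth_pmf):
        raise ValueError("model and truth pmfs must share a common support length")
    t = truth_pmf.probs
    m = model_pmf.probs
    mask = t > 0
    if np.any(m[mask] <= 0):
        return float("inf")
    return float(-np.sum(t[mask] * np.log(m[mask])))


def _cross_entropy_logp(truth_probs: np.ndarray, logp: np.ndarray) -> float:
    mask = truth_probs > 0
    if not np.all(np.isfinite(logp[mask])):
        return float("inf")
    return float(-np.sum(truth_probs[mask] * logp[mask]))


# ---------------------------------------------------------------------------
# candidate log-pmfs (standard and capture-corrected)
# ---------------------------------------------------------------------------

def _candidate_log_pmf(kind: str, theta, capture: CaptureModel | None, n_max: int):
    """log P(n|theta) for a candidate, marginalized over ``capture`` if given.

    Standard candidates ignore the capture model entirely.  Point captures
    reduce to exact rate rescalings; Beta captures use the closed forms.
    """
    if capture is None:
        if kind == "telegraph":
            return telegraph_log_pmf(TelegraphParams(*theta), n_max)
        if kind == "nb":
            return stats.nbinom.logpmf(np.arange(n_max + 1), *theta)
        return stats.poisson.logpmf(np.arange(n_max + 1), theta[0])
    if capture.variant == "point":
        pc = capture.pcap
        if kind == "telegraph":
            rho, son, soff = theta
            return telegraph_log_pmf(TelegraphParams(rho * pc, son, soff), n_max)
        if kind == "nb":
            r, p = theta
            c = pc * (1.0 - p) / p
            return stats.nbinom.logpmf(np.arange(n_max + 1), r, 1.0 / (1.0 + c))
        return stats.poisson.logpmf(np.arange(n_max + 1), theta[0] * pc)
    if capture.variant == "beta":
        if kind == "telegraph":
            return _tele_beta_log_quad(TelegraphParams(*theta), capture.a, capture.b, n_max)
        if kind == "nb":
            pv = observed_pmf_nb_beta(NBParams(*theta), capture, n_max=n_max)
        else:
            pv = observed_pmf_poisson_beta(PoissonParams(theta[0]), capture, n_max=n_max)
        with np.errstate(divide="ignore"):
            return np.log(pv.probs)
    raise ValueError("empirical capture models are handled by marginal_pmf_over_density")


# ---------------------------------------------------------------------------
# population fits (against an exact truth pmf)
# ---------------------------------------------------------------------------

def _thinned_moment_inverse(mean_t: float, var_t: float, capture: CaptureModel | None):
    """Invert binomial-thinning moment maps: given observed mean/variance,
    return the (mean, factorial-second-moment) of the *underlying* model."""
    if capture is None:
        return mean_t, var_t + mean_t**2 - mean_t
    mp_, cv = capture.mean_pcap, capture.cv_pcap
    ep2 = mp_**2 * (1.0 + cv**2)
    mu = mean_t / mp_
    fac2 = (var_t + mean_t**2 - mean_t) / ep2  # E[n (n-1)] of the true counts
    return mu, fac2


def _mom_nb(mean_t, var_t, capture):
    mu, fac2 = _thinned_moment_inverse(mean_t, var_t, capture)
    denom = fac2 - mu**2
    if denom <= 0 or mu <= 0:
        return None  # under-dispersed: no valid NB moment match
    r = mu**2 / denom
    c = mu / r
    return NBParams(r=r, p=1.0 / (1.0 + c))


def _telegraph_mle_starts(mean_t, var_t, capture, x0=None):
    mp_ = capture.mean_pcap if capture is not None else 1.0
    mu = max(mean_t / mp_, 1e-6)
    if x0 is None:
        x0 = (2.0 * mu, 1.0, 1.0)
    x0 = np.asarray(x0, dtype=float)
    return [x0, x0 * np.array([0.5, 2.0, 0.5]), x0 * np.array([2.0, 0.5, 2.0])]


def _tele_objective(truth_probs, capture):
    n_max = truth_probs.size - 1

    def objective(logtheta):
        theta = np.exp(logtheta)
        # box keeps the search inside the numerically comfortable region;
        # beyond N_sigma ~ 1e4 the telegraph pmf is Poisson to ~1e-8 anyway
        if np.any(theta > 1e4) or np.any(theta < 1e-8):
            return 1e6
        try:
            logp = _candidate_log_pmf("telegraph", tuple(theta), capture, n_max)
        except (FloatingPointError, ValueError):
            return 1e6
        val = _cross_entropy_logp(truth_probs, logp)
        return val if math.isfinite(val) else 1e6

    return objective


def _fit_telegraph_mle(truth_probs, capture, starts, maxiter=2000, fatol=1e-10,
                       xatol=1e-6, agree_tol=None):
    """Nelder-Mead cross-entropy minimization over (log rho, log s_on, log s_off).

    ``agree_tol`` enables early stopping in scans: once two starts agree to
    within it, remaining starts are skipped.
    """
    objective = _tele_objective(truth_probs, capture)
    best = None
    funs = []
    for s in starts:
        res = optimize.minimize(
            objective, np.log(s), method="Nelder-Mead",
            options={"fatol": fatol, "xatol": xatol, "maxiter": maxiter, "maxfev": maxiter},
        )
        funs.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
        if agree_tol is not None and len(funs) >= 2:
            if abs(sorted(funs)[0] - sorted(funs)[1]) < agree_tol:
                break
    theta = tuple(np.exp(best.x))
    return theta, float(best.fun), bool(best.success)


def fit_model_to_pmf(model: CandidateModel, truth_pmf: PMFVector, method: str = "mom",
                     capture: CaptureModel | None = None,
                     truth_moments: tuple[float, float] | None = None,
                     x0=None) -> FitResult:
    """Fit a candidate model to an exact ground-truth pmf.

    ``method='mom'`` matches moments (Poisson: mean; NB: mean and variance,
    which for a telegraph truth reproduces the effective NB exactly);
    ``method='mle'`` minimizes the cross entropy with Nelder-Mead from three
    deterministic starts.  The telegraph candidate is always fitted by
    cross-entropy minimization, since its three parameters are not determined
    by two moments.  ``capture`` must be supplied for corrected candidates.
    """
    if model.corrected and capture is None:
        raise ValueError("corrected candidates require a capture model")
    cap = capture if model.corrected else None
    t = truth_pmf.probs
    n_max = t.size - 1
    if truth_moments is not None:
        mean_t, var_t = truth_moments
    else:
        mean_t, var_t = truth_pmf.mean(), truth_pmf.variance()

    if model.kind == "telegraph" or method == "mle":
        if model.kind == "poisson":
            # 1-D problem: the mean is also the population MLE start; polish it
            lam0 = mean_t / (cap.mean_pcap if cap is not None else 1.0)
            res = optimize.minimize_scalar(
                lambda loglam: _cross_entropy_logp(
                    t, _candidate_log_pmf("poisson", (math.exp(loglam),), cap, n_max)
                ),
                bracket=(math.log(lam0) - 0.3, math.log(lam0) + 0.3),
                method="brent", options={"xtol": 1e-10},
            )
            return FitResult(model, (math.exp(res.x),), float(res.fun), method="mle")
        if model.kind == "nb":
            nb0 = _mom_nb(mean_t, var_t, cap)
            x0_nb = (nb0.r, nb0.p) if nb0 else (1.0, 0.5)

            def obj(z):
                r, p = math.exp(z[0]), 1.0 / (1.0 + math.exp(-z[1]))
                val = _cross_entropy_logp(
                    t, _candidate_log_pmf("nb", (r, p), cap, n_max)
                )
                return val if math.isfinite(val) else 1e6

            z0 = [math.log(x0_nb[0]), math.log(x0_nb[1] / (1.0 - x0_nb[1]))]
            res = optimize.minimize(obj, z0, method="Nelder-Mead",
                                    options={"fatol": 1e-10, "xatol": 1e-7, "maxiter": 2000})
            theta = (math.exp(res.x[0]), 1.0 / (1.0 + math.exp(-res.x[1])))
            return FitResult(model, theta, float(res.fun), method="mle",
                             converged=bool(res.success))
        starts = _telegraph_mle_starts(mean_t, var_t, cap, x0=x0)
        theta, eps, ok = _fit_telegraph_mle(t, cap, starts)
        return FitResult(model, theta, eps, method="mle", converged=ok)

    # method of moments
    if model.kind == "poisson":
        lam = mean_t / (cap.mean_pcap if cap is not None else 1.0)
        logp = _candidate_log_pmf("poisson", (lam,), cap, n_max)
        return FitResult(model, (lam,), _cross_entropy_logp(t, logp), method="mom")
    nb = _mom_nb(mean_t, var_t, cap)
    if nb is None:
        return FitResult(model, (float("nan"), float("nan")), float("inf"),
                         method="mom", converged=False)
    logp = _candidate_log_pmf("nb", (nb.r, nb.p), cap, n_max)
    return FitResult(model, (nb.r, nb.p), _cross_entropy_logp(t, logp), method="mom")


def aebic(fit: FitResult, nc: int) -> float:
    """aeBIC = |M| ln nc + 2 nc eps_c."""
    if nc < 2:
        raise ValueError("nc must be >= 2")
    return fit.model.n_params * math.log(nc) + 2.0 * nc * fit.cross_entropy


# ---------------------------------------------------------------------------
# sample-based fits
# ---------------------------------------------------------------------------

def _sample_neg_loglik(kind, theta, capture, values, weights, n_max):
    logp = _candidate_log_pmf(kind, theta, capture, n_max)
    lv = logp[values]
    if not np.all(np.isfinite(lv)):
        return float("inf")
    return float(-(weights * lv).sum())


def bic(model: CandidateModel, counts, capture: CaptureModel | None = None) -> FitResult:
    """Sample-based BIC: |M| ln nc - 2 max log-likelihood, fitted by MLE.

    Degenerate all-zero data: Poisson and NB return boundary estimates; the
    telegraph model is flagged non-converged (unidentifiable).
    """
    counts = np.asarray(counts)
    if counts.size == 0 or np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be a nonempty array of nonnegative integers")
    nc = counts.size
    values, weights = np.unique(counts, return_counts=True)
    n_max = int(values.max())
    cap = capture if model.corrected else None
    mean, var = counts.mean(), counts.var()
    pen = model.n_params * math.log(nc)

    if mean == 0:
        if model.kind == "telegraph":
            return FitResult(model, (0.0, 1.0, 1.0), 0.0, criterion=pen,
                             converged=False, log_likelihood=0.0)
        theta = (0.0,) if model.kind == "poisson" else (1.0, 1.0 - 1e-12)
        return FitResult(model, theta, 0.0, criterion=pen, converged=True,
                         log_likelihood=0.0)

    if model.kind == "poisson" and cap is None:
        lam = float(mean)  # closed-form MLE
        nll = _sample_neg_loglik("poisson", (lam,), None, values, weights, n_max)
        return FitResult(model, (lam,), nll / nc, criterion=pen + 2.0 * nll,
                         method="mle", log_likelihood=-nll)

    if model.kind == "poisson":
        lam0 = mean / cap.mean_pcap
        res = optimize.minimize_scalar(
            lambda z: _sample_neg_loglik("poisson", (math.exp(z),), cap, values, weights, n_max),
            bracket=(math.log(lam0) - 0.3, math.log(lam0) + 0.3), method="brent",
            options={"xtol": 1e-10},
        )
        nll = float(res.fun)
        return FitResult(model, (math.exp(res.x),), nll / nc, criterion=pen + 2.0 * nll,
                         method="mle", log_likelihood=-nll)

    if model.kind == "nb":
        nb0 = _mom_nb(mean, var, cap) or NBParams(1.0, 0.5)

        def obj(z):
            # clamp to keep nbinom.logpmf finite on the Poisson boundary p -> 1
            r = math.exp(min(max(z[0], -18.0), 14.0))
            p = 1.0 / (1.0 + math.exp(-min(max(z[1], -30.0), 30.0)))
            v = _sample_neg_loglik("nb", (r, p), cap, values, weights, n_max)
            return v if math.isfinite(v) else 1e12

        z0 = [math.log(nb0.r), math.log(nb0.p / (1.0 - nb0.p))]
        res = optimize.minimize(obj, z0, method="Nelder-Mead",
                                options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000})
        theta = (math.exp(min(max(res.x[0], -18.0), 14.0)),
                 1.0 / (1.0 + math.exp(-min(max(res.x[1], -30.0), 30.0))))
        nll = float(res.fun)
        return FitResult(model, theta, nll / nc, criterion=pen + 2.0 * nll,
                         method="mle", converged=bool(res.success), log_likelihood=-nll)

    # telegraph
    starts = _telegraph_mle_starts(mean, var, cap)

    def obj(z):
        theta = np.exp(z)
        if np.any(theta > 1e4) or np.any(theta < 1e-8):
            return 1e12
        try:
            v = _sample_neg_loglik("telegraph", tuple(theta), cap, values, weights, n_max)
        except (FloatingPointError, ValueError):
            return 1e12
        return v if math.isfinite(v) else 1e12

    best = None
    for s in starts:
        res = optimize.minimize(obj, np.log(s), method="Nelder-Mead",
                                options={"fatol": 1e-8, "xatol": 1e-5, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    nll = float(best.fun)
    return FitResult(model, tuple(np.exp(best.x)), nll / nc, criterion=pen + 2.0 * nll,
                     method="mle", converged=bool(best.success), log_likelihood=-nll)


def expected_bic_mc(truth_pmf: PMFVector, model: CandidateModel, nc: int,
                    n_trials: int, seed, capture: CaptureModel | None = None):
    """Monte-Carlo estimate of E[BIC]: mean and standard error over
    ``n_trials`` independent datasets of ``nc`` counts drawn from the truth."""
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 for a standard error")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = truth_pmf.probs / truth_pmf.probs.sum()
    support = np.arange(p.size)
    vals = np.empty(n_trials)
    for t in range(n_trials):
        counts = rng.choice(support, size=nc, p=p)
        vals[t] = bic(model, counts, capture=capture).criterion
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_trials))


def select_best(truth_pmf: PMFVector, nc: int, candidates, method: str = "mom",
                capture: CaptureModel | None = None,
                truth_moments: tuple[float, float] | None = None,
                return_fits: bool = False):
    """Candidate with the smallest aeBIC; ties go to the fewest parameters."""
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    fits = {}
    for cand in candidates:
        try:
            f = fit_model_to_pmf(cand, truth_pmf, method=method, capture=capture,
                                 truth_moments=truth_moments)
            f.criterion = aebic(f, nc)
        except Exception as exc:  # noqa: BLE001 - per-candidate failures are data
            _log.warning("fit of %s failed: %s", cand, exc)
            f = FitResult(cand, (), float("inf"), criterion=float("inf"), converged=False)
        fits[cand] = f
    finite = {c: f for c, f in fits.items() if math.isfinite(f.criterion)}
    if not finite:
        raise RuntimeError("all candidate fits failed")
    best = min(finite, key=lambda c: (finite[c].criterion, c.n_params))
    return (best, fits) if return_fits else best


# ---------------------------------------------------------------------------
# phase scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseGrid:
    """Scan grid: log-spaced N_sigma by linear f_on."""

    nsigma_min: float = 0.1
    nsigma_max: float = 1000.0
    n_nsigma: int = 206
    fon_min: float = 0.005
    fon_max: float = 0.995
    n_fon: int = 100

    def __post_init__(self):
        if not (0 < self.nsigma_min < self.nsigma_max):
            raise ValueError("need 0 < nsigma_min < nsigma_max")
        if not (0.0 < self.fon_min < self.fon_max < 1.0):
            raise ValueError("f_on range must lie inside (0, 1)")
        if self.n_nsigma < 2 or self.n_fon < 2:
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def nsigma_axis(self) -> np.ndarray:
        return np.geomspace(self.nsigma_min, self.nsigma_max, self.n_nsigma)

    @property
    def fon_axis(self) -> np.ndarray:
        return np.linspace(self.fon_min, self.fon_max, self.n_fon)

    @property
    def n_points(self) -> int:
        return self.n_nsigma * self.n_fon


@dataclass
class EntropyScan:
    """Per-grid-point minimized cross entropies for the three candidates.

    The fitted cross entropies do not depend on the sample size, so one scan
    serves every nc via :meth:`PhaseDiagram.from_entropy_scan`.
    """

    grid: PhaseGrid
    rho: float
    eps: np.ndarray  # (n_nsigma, n_fon, 3) in MODEL_KINDS order
    truth_capture: CaptureModel | None
    corrected: bool
    method: str
    n_failed: int = 0
    nc_hints: tuple[int, ...] | None = None


def _truth_pmf_point(tp: TelegraphParams, truth_capture, trunc_mass=1.0 - 1e-10):
    """Truth pmf (truncated to cumulative mass > ``trunc_mass``) and its exact
    observed moments; flags whether the truth is itself a telegraph pmf."""
    if truth_capture is None or truth_capture.variant == "point":
        pc = 1.0 if truth_capture is None else truth_capture.pcap
        eff = TelegraphParams(tp.rho * pc, tp.sigma_on, tp.sigma_off)
        pv = telegraph_pmf(eff)
        m, v = telegraph_moments(eff)
        is_tele = True
    elif truth_capture.variant == "beta":
        m, v, _ = observed_moments_telegraph_beta(tp, truth_capture)
        from .distributions import _auto_nmax, _extend_until_normalized

        probs = _extend_until_normalized(
            lambda k: _tele_beta_log_quad(tp, truth_capture.a, truth_capture.b, k),
            _auto_nmax(m, v, None), 1e-10,
        )
        pv = PMFVector(probs, check=False)
        is_tele = False
    else:
        raise ValueError("truth capture must be none, point or beta for scans")
    return pv.truncate_to_mass(trunc_mass), (m, v), is_tele


def _scan_point(tp: TelegraphParams, truth_capture, corrected: bool, method: str,
                warm=None, nc_hints=None):
    truth, (m, v), truth_is_tele = _truth_pmf_point(tp, truth_capture)
    t = truth.probs
    n_max = t.size - 1
    H = entropy(truth)
    cap = truth_capture if corrected else None
    if corrected and truth_capture is None:
        cap = None

    if method == "mom":
        nb = _mom_nb(m, v, cap)
        if nb is None:
            eps_nb = float("inf")
        else:
            eps_nb = _cross_entropy_logp(t, _candidate_log_pmf("nb", (nb.r, nb.p), cap, n_max))
        lam = m / (cap.mean_pcap if cap is not None else 1.0)
        eps_pois = _cross_entropy_logp(t, _candidate_log_pmf("poisson", (lam,), cap, n_max))
    else:
        eps_nb = fit_model_to_pmf(CandidateModel("nb", corrected), truth, method="mle",
                                  capture=cap, truth_moments=(m, v)).cross_entropy
        eps_pois = fit_model_to_pmf(CandidateModel("poisson", corrected), truth,
                                    method="mle", capture=cap,
                                    truth_moments=(m, v)).cross_entropy

    # telegraph candidate: exact self-fit whenever its family contains the truth
    theta_tele = (tp.rho, tp.sigma_on, tp.sigma_off)
    if (not corrected and truth_is_tele) or corrected:
        eps_tele = H
    elif nc_hints and all(
        3.0 * math.log(nc) + 2.0 * nc * H
        > min(2.0 * math.log(nc) + 2.0 * nc * eps_nb,
              math.log(nc) + 2.0 * nc * eps_pois)
        for nc in nc_hints
    ):
        # even a perfect telegraph fit (eps_c = truth entropy, its lower
        # bound) loses at every hinted sample size; skip the numeric MLE and
        # store the bound, which leaves the winner unchanged at those nc
        eps_tele = H
        theta_tele = warm
    else:
        pc = truth_capture.mean_pcap if truth_capture is not None else 1.0
        s0 = np.array([tp.rho * pc, tp.sigma_on, tp.sigma_off])
        starts = ([np.asarray(warm, dtype=float)] if warm is not None else []) + [
            s0,
            s0 * np.array([2.0, 0.5, 2.0]),
        ]
        # scan-local tolerances: the selection threshold is ln(nc)/(2 nc), so
        # cross entropies only need ~1e-5 accuracy here
        theta_tele, eps_tele, _ = _fit_telegraph_mle(
            t, None, starts, maxiter=300, fatol=1e-9, xatol=1e-4, agree_tol=1e-6
        )
    return (eps_tele, eps_nb, eps_pois), theta_tele


def cross_entropy_scan(grid: PhaseGrid, rho: float,
                       truth_capture: CaptureModel | None = None,
                       candidate_capture: str = "standard",
                       method: str = "mom", progress: bool = False,
                       nc_hints=None) -> EntropyScan:
    """Minimized cross entropy of each candidate at every (N_sigma, f_on).

    ``candidate_capture`` is "standard" (candidates ignore technical noise)
    or "corrected" (candidate pmfs are integrated over ``truth_capture``).
    ``method`` selects MOM or MLE fitting for the NB and Poisson candidates;
    the telegraph candidate is always fitted by cross-entropy minimization
    (exactly, when its family contains the truth).

    ``nc_hints`` optionally restricts the scan to a known set of sample
    sizes: at grid points where even a perfect telegraph fit cannot win at
    any hinted nc, the expensive telegraph MLE is skipped and its entropy
    lower bound recorded instead.  A hinted scan must only be turned into
    phase diagrams at those sample sizes.
    """
    if candidate_capture not in ("standard", "corrected"):
        raise ValueError("candidate_capture must be 'standard' or 'corrected'")
    corrected = candidate_capture == "corrected"
    ns_ax, fon_ax = grid.nsigma_axis, grid.fon_axis
    eps = np.full((ns_ax.size, fon_ax.size, 3), np.nan)
    n_failed = 0
    for i, ns in enumerate(ns_ax):
        warm = None  # warm-start the telegraph MLE along each N_sigma row
        for j, fo in enumerate(fon_ax):
            tp = TelegraphParams.from_fon_nsigma(rho, fo, ns)
            try:
                eps[i, j, :], warm = _scan_point(tp, truth_capture, corrected,
                                                 method, warm=warm, nc_hints=nc_hints)
            except Exception as exc:  # noqa: BLE001 - record and continue
                n_failed += 1
                warm = None
                _log.warning("scan point (N=%g, f=%g) failed: %s", ns, fo, exc)
        if progress:
            print(f"\r  scan {i + 1}/{ns_ax.size}", end="", flush=True)
    if progress:
        print()
    if n_failed:
        _log.warning("%d grid points failed and are excluded from fractions", n_failed)
    return EntropyScan(grid=grid, rho=rho, eps=eps, truth_capture=truth_capture,
                       corrected=corrected, method=method, n_failed=n_failed,
                       nc_hints=tuple(nc_hints) if nc_hints else None)


@dataclass
class PhaseDiagram:
    """Winning model per (N_sigma, f_on) grid point and area fractions."""

    nsigma_axis: np.ndarray
    fon_axis: np.ndarray
    winner: np.ndarray       # int codes into MODEL_KINDS; -1 = invalid
    aebic_values: np.ndarray  # (n_nsigma, n_fon, 3)
    nc: int
    rho: float
    corrected: bool = False

    @classmethod
    def from_entropy_scan(cls, scan: EntropyScan, nc: int) -> "PhaseDiagram":
        if scan.nc_hints is not None and nc not in scan.nc_hints:
            raise ValueError(
                f"scan was computed with nc_hints={scan.nc_hints}; "
                f"a diagram at nc={nc} would be unreliable"
            )
        pen = np.array([_N_PARAMS[k] for k in MODEL_KINDS]) * math.log(nc)
        crit = pen[None, None, :] + 2.0 * nc * scan.eps
        safe = np.where(np.isfinite(crit), crit, np.inf)
        # ties favor fewer parameters: scan kinds from poisson down to telegraph
        win = np.full(safe.shape[:2], -1, dtype=np.int8)
        best = np.full(safe.shape[:2], np.inf)
        for k in (2, 1, 0):
            better = safe[:, :, k] < best
            win[better] = k
            best[better] = safe[:, :, k][better]
        return cls(nsigma_axis=scan.grid.nsigma_axis, fon_axis=scan.grid.fon_axis,
                   winner=win, aebic_values=crit, nc=nc, rho=scan.rho,
                   corrected=scan.corrected)

    @property
    def fractions(self) -> dict[str, float]:
        valid = self.winner >= 0
        total = int(valid.sum())
        if total == 0:
            raise RuntimeError("no valid grid points")
        return {
            kind: 100.0 * float((self.winner == k).sum()) / total
            for k, kind in enumerate(MODEL_KINDS)
        }

    def mask(self, kind: str) -> np.ndarray:
        return self.winner == MODEL_KINDS.index(kind)

    def to_tsv(self, path) -> None:
        import pandas as pd

        ns, fo = np.meshgrid(self.nsigma_axis, self.fon_axis, indexing="ij")
        win = np.array(["invalid"] + list(MODEL_KINDS))[self.winner.ravel() + 1]
        pd.DataFrame({
            "N_sigma": ns.ravel(), "f_on": fo.ravel(), "winner": win,
            "aeBIC_tele": self.aebic_values[:, :, 0].ravel(),
            "aeBIC_nb": self.aebic_values[:, :, 1].ravel(),
            "aeBIC_pois": self.aebic_values[:, :, 2].ravel(),
        }).to_csv(path, sep="\t", index=False)

    def fractions_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"nc": self.nc, "rho": self.rho, "corrected": self.corrected,
                       "fractions_pct": self.fractions}, fh, indent=2)

    def plot(self, path=None):
        """Optional raster phase plot (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        fig, ax = plt.subplots(figsize=(5, 4))
        cmap = ListedColormap(["#888888", "#4c72b0", "#dd8452", "#55a868"])
        ax.pcolormesh(self.nsigma_axis, self.fon_axis, self.winner.T + 1,
                      cmap=cmap, vmin=0, vmax=3, shading="nearest")
        ax.set_xscale("log")
        ax.set_xlabel(r"$N_\sigma$")
        ax.set_ylabel(r"$f_{on}$")
        fr = self.fractions
        ax.set_title(f"nc={self.nc}  tele/NB/Pois = "
                     f"{fr['telegraph']:.1f}/{fr['nb']:.1f}/{fr['poisson']:.1f}%")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def phase_scan(grid: PhaseGrid, rho: float, nc: int,
               truth_capture: CaptureModel | None = None,
               candidate_capture: str = "standard", method: str = "mom",
               progress: bool = False) -> PhaseDiagram:
    """Full (N_sigma, f_on) model-selection scan at sample size ``nc``.

    The ground truth at each grid point is the telegraph pmf (optionally
    downsampled by ``truth_capture``); the winner is the candidate with the
    smallest aeBIC.  For several sample sizes, compute
    :func:`cross_entropy_scan` once and reuse it via
    :meth:`PhaseDiagram.from_entropy_scan`.
    """
    scan = cross_entropy_scan(grid, rho, truth_capture=truth_capture,
                              candidate_capture=candidate_capture, method=method,
                              progress=progress)
    return PhaseDiagram.from_entropy_scan(scan, nc)
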