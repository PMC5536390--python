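"""Per-clade diversification-rate estimation.

Two routes are provided:

* the crown-group method-of-moments estimator of net diversification,
  which inverts the expected richness of a surviving crown clade of known
  age under an assumed relative extinction fraction ``eps = mu/lambda``;

* maximum-likelihood fitting of six time-dependent birth-death models to a
  clade's branching times under uniform incomplete sampling, with AIC-based
  model selection.  Rates are parameterised in time before present,
  ``lambda(tau) = lambda0 * exp(alpha * tau)`` and
  ``mu(tau) = mu0 * exp(beta * tau)``, so "rate at present" is simply
  ``lambda0`` (and net diversification at present ``lambda0 - mu0``).

The likelihood is that of the reconstructed tree conditioned on survival of
both crown lineages.  Writing ``R(t) = int_0^t (lambda - mu)`` and
``D(t) = 1/f + int_0^t lambda(s) exp(R(s)) ds`` it takes the form

    log L = -2 log(f D(t1)) + sum_{i>=2} [log lambda(t_i) + R(t_i)
                                          - log f - 2 log D(t_i)]

where ``t1`` is the crown age and ``t_i`` the younger branching times.
Constant-rate models use the closed form of ``D``; exponential-rate models
integrate ``lambda e^R`` with fixed-order Gauss-Legendre panels between
consecutive branching times (the integrand is smooth, so a 24-point panel
is accurate far beyond optimizer tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .phylo import Phylogeny

__all__ = [
    "MODELS",
    "DiversificationFit",
    "mom_diversification",
    "expected_crown_richness",
    "bd_loglik",
    "fit_bd_models",
    "present_rates",
]

# model id -> free parameters (subset of lam0, alpha, mu0, beta)
MODELS: dict[str, tuple[str, ...]] = {
    "pb_const": ("lam0",),
    "pb_exp": ("lam0", "alpha"),
    "bd_const": ("lam0", "mu0"),
    "bd_expl_cstmu": ("lam0", "alpha", "mu0"),
    "bd_cstl_expmu": ("lam0", "mu0", "beta"),
    "bd_expl_expmu": ("lam0", "alpha", "mu0", "beta"),
}


# ----------------------------------------------------------------------
# method of moments
# ----------------------------------------------------------------------
def expected_crown_richness(r: float, eps: float, t: float) -> float:
    """Expected present-day richness of a crown clade of age ``t``.

    Constant-rate birth-death with net rate ``r`` and relative extinction
    ``eps``, starting from the two crown lineages and conditioned on the
    clade having at least one extant descendant:

        E[n] = 2 (x - eps)^2 / [(1 - eps) (x (1 + eps) - 2 eps)],
        x = exp(r t).
    """
    x = math.exp(r * t)
    if eps == 0.0:
        return 2.0 * x
    return 2.0 * (x - eps) ** 2 / ((1.0 - eps) * (x * (1.0 + eps) - 2.0 * eps))


def mom_diversification(t: float, n: float, eps: float) -> float:
    """Crown-group method-of-moments estimate of net diversification.

    Solves ``expected_crown_richness(r, eps, t) = n`` for ``r`` in closed
    form.  For ``eps = 0`` this reduces to ``log(n/2) / t``.

    Parameters
    ----------
    t: crown age in Myr (> 0).
    n: total (described) species richness of the clade (>= 2).
    eps: assumed relative extinction fraction mu/lambda in [0, 1).

    Returns
    -------
    Net diversification rate in events / lineage / Myr.
    """
    if t <= 0:
        raise ValueError(f"crown age must be positive, got {t}")
    if n < 2:
        raise ValueError(f"richness must be >= 2, got {n}")
    if not (0.0 <= eps < 1.0):
        raise ValueError(f"relative extinction must be in [0, 1), got {eps}")
    if eps == 0.0:
        return math.log(n / 2.0) / t
    inner = (
        0.5 * n * (1.0 - eps**2)
        + 2.0 * eps
        + 0.5
        * (1.0 - eps)
        * math.sqrt(n * (n * eps**2 + 2.0 * n * eps + n - 8.0 * eps))
    )
    return (math.log(inner) - math.log(2.0)) / t


def mom_invert_numeric(t: float, n: float, eps: float) -> float:
    """Numerical inversion of :func:`expected_crown_richness` (oracle route)."""
    fun = lambda r: expected_crown_richness(r, eps, t) - n
    hi = max(1.0, math.log(n) / t * 4 + 1.0)
    lo = -hi
    while fun(hi) < 0:
        hi *= 2.0
    return brentq(fun, lo, hi, xtol=1e-12, rtol=1e-14)


# ----------------------------------------------------------------------
# time-varying birth-death likelihood
# ----------------------------------------------------------------------
def _rate_integral(rate0: float, expo: float, t: np.ndarray) -> np.ndarray:
    """``int_0^t rate0 * exp(expo * s) ds`` elementwise."""
    t = np.asarray(t, dtype=float)
    if expo == 0.0:
        return rate0 * t
    return rate0 * np.expm1(expo * t) / expo

# Gauss-Legendre nodes/weights on [0, 1], fixed order
_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


def _cumulative_D(
    times: np.ndarray, lam0: float, alpha: float, mu0: float, beta: float, f: float
) -> np.ndarray:
    """``D(t) = 1/f + int_0^t lambda(s) e^{R(s)} ds`` at each of ``times``.

    ``times`` must be sorted ascending.  Closed form when both rates are
    constant; Gauss-Legendre panels between consecutive times otherwise.
    """
    if alpha == 0.0 and beta == 0.0:
        r = lam0 - mu0
        if abs(r) < 1e-12:
            return 1.0 / f + lam0 * times
        return 1.0 / f + lam0 * np.expm1(r * times) / r
    bounds = np.concatenate([[0.0], times])
    a, b = bounds[:-1], bounds[1:]
    width = b - a
    # panel nodes: (n_seg, n_gl)
    s = a[:, None] + width[:, None] * _GL_X[None, :]
    R = _rate_integral(lam0, alpha, s) - _rate_integral(mu0, beta, s)
    lam_s = lam0 * np.exp(alpha * s)
    seg = width * np.einsum("ij,j->i", lam_s * np.exp(R), _GL_W)
    return 1.0 / f + np.cumsum(seg)


def bd_loglik(
    branching_times,
    lam0: float,
    alpha: float = 0.0,
    mu0: float = 0.0,
    beta: float = 0.0,
    f: float = 1.0,
) -> float:
    """Log-likelihood of a reconstructed tree's branching times.

    Parameters
    ----------
    branching_times:
        Ages (Myr before present) of all internal nodes including the crown
        node; order is irrelevant.
    lam0, alpha, mu0, beta:
        Speciation/extinction parameters, time-before-present convention.
    f:
        Uniform sampling probability of extant species, in (0, 1].

    The likelihood is conditioned on both crown lineages surviving to the
    present and leaving sampled descendants.
    """
    if lam0 <= 0:
        raise ValueError(f"lam0 must be positive, got {lam0}")
    if mu0 < 0:
        raise ValueError(f"mu0 must be nonnegative, got {mu0}")
    if not (0.0 < f <= 1.0):
        raise ValueError(f"sampling fraction must be in (0, 1], got {f}")
    times = np.sort(np.asarray(branching_times, dtype=float))
    if times.size < 1 or times[-1] <= 0:
        raise ValueError("need at least the crown branching time (> 0)")
    with np.errstate(over="raise"):
        try:
            D = _cumulative_D(times, lam0, alpha, mu0, beta, f)
            R = _rate_integral(lam0, alpha, times) - _rate_integral(mu0, beta, times)
        except FloatingPointError:
            return -np.inf
    crown_D = D[-1]
    inner = times[:-1]
    inner_D = D[:-1]
    lam_t = lam0 * np.exp(alpha * inner)
    ll = -2.0 * math.log(f * crown_D)
    ll += float(
        np.sum(np.log(lam_t) + R[:-1] - math.log(f) - 2.0 * np.log(inner_D))
    )
    if not np.isfinite(ll):
        return -np.inf
    return ll


# ----------------------------------------------------------------------
# model fitting
# ----------------------------------------------------------------------
@dataclass
class DiversificationFit:
    model: str
    params: dict[str, float]
    loglik: float
    aic: float
    lambda0: float
    mu_present: float
    r_present: float
    converged: bool
    restarts: int = 0
    seed: int | None = None

    @property
    def n_params(self) -> int:
        return len(MODELS[self.model])


_BOUNDS = {
    "log_lam0": (math.log(1e-4), math.log(10.0)),
    "alpha": (-1.0, 1.0),
    "log_mu0": (math.log(1e-6), math.log(10.0)),
    "beta": (-1.0, 1.0),
}


def _fit_one_model(
    model: str,
    times: np.ndarray,
    f: float,
    rng: np.random.Generator,
    n_restarts: int,
    warm_starts: list[dict] | None = None,
) -> DiversificationFit:
    free = MODELS[model]
    use_alpha = "alpha" in free
    use_mu = "mu0" in free
    use_beta = "beta" in free

    def unpack(theta):
        i = 0
        lam0 = math.exp(theta[i]); i += 1
        alpha = theta[i] if use_alpha else 0.0
        i += use_alpha
        mu0 = math.exp(theta[i]) if use_mu else 0.0
        i += use_mu
        beta = theta[i] if use_beta else 0.0
        return lam0, alpha, mu0, beta

    def nll(theta):
        lam0, alpha, mu0, beta = unpack(theta)
        ll = bd_loglik(times, lam0, alpha, mu0, beta, f=f)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [_BOUNDS["log_lam0"]]
    if use_alpha:
        bounds.append(_BOUNDS["alpha"])
    if use_mu:
        bounds.append(_BOUNDS["log_mu0"])
    if use_beta:
        bounds.append(_BOUNDS["beta"])

    # heuristic start: Yule-ish rate from tip count and crown age
    n_tips = times.size + 1
    lam_guess = max(math.log(max(n_tips / f, 3.0) / 2.0) / times.max(), 1e-3)
    starts = [np.array([math.log(lam_guess)] + [0.0] * use_alpha
                       + [math.log(lam_guess / 2.0)] * use_mu + [0.0] * use_beta)]
    for _ in range(n_restarts - 1):
        theta = [math.log(lam_guess) + rng.normal(0, 0.7)]
        if use_alpha:
            theta.append(rng.normal(0, 0.1))
        if use_mu:
            theta.append(math.log(lam_guess) + rng.normal(-1.0, 1.0))
        if use_beta:
            theta.append(rng.normal(0, 0.1))
        starts.append(np.array(theta))
    # warm starts from already-fitted nested submodels guarantee likelihood
    # dominance of richer models within optimizer tolerance
    for params in warm_starts or []:
        theta = [math.log(max(params["lam0"], 1e-4))]
        if use_alpha:
            theta.append(params["alpha"])
        if use_mu:
            theta.append(math.log(max(params["mu0"], 1e-6)))
        if use_beta:
            theta.append(params["beta"])
        starts.append(np.array(theta))

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam0, alpha, mu0, beta = unpack(best.x)
    ll = -best.fun
    converged = bool(best.success) and ll > -1e11
    k = len(free)
    params = {"lam0": lam0, "alpha": alpha, "mu0": mu0, "beta": beta}
    return DiversificationFit(
        model=model,
        params={p: params[p] for p in ("lam0", "alpha", "mu0", "beta")},
        loglik=ll,
        aic=2.0 * k - 2.0 * ll if converged else math.inf,
        lambda0=lam0,
        mu_present=mu0,
        r_present=lam0 - mu0,
        converged=converged,
        restarts=len(starts),
    )


def fit_bd_models(
    clade_tree: Phylogeny,
    f: float = 1.0,
    models: tuple[str, ...] | None = None,
    n_restarts: int = 3,
    min_tips: int = 4,
    seed: int | None = None,
) -> list[DiversificationFit]:
    """Fit the six birth-death models to a clade and sort by AIC.

    Returns all fits sorted ascending by AIC (failed fits, flagged
    ``converged=False``, sort last); ``fits[0]`` is the selected model.
    """
    if clade_tree.n_tips < min_tips:
        raise ValueError(
            f"clade has {clade_tree.n_tips} tips; minimum is {min_tips}"
        )
    times = clade_tree.branching_times()
    rng = np.random.default_rng(seed)
    fits = []
    done: dict[str, DiversificationFit] = {}
    for m in (models or tuple(MODELS)):
        free = set(MODELS[m])
        warm = [x.params for prev, x in done.items()
                if set(MODELS[prev]) < free and x.converged]
        fit = _fit_one_model(m, times, f, rng, n_restarts, warm_starts=warm)
        done[m] = fit
        fits.append(fit)
    for fit in fits:
        fit.seed = seed
    if all(not fit.converged for fit in fits):
        raise RuntimeError("all diversification model fits failed to converge")
    fits.sort(key=lambda fit: fit.aic)
    return fits


def present_rates(fit: DiversificationFit) -> tuple[float, float, float]:
    """Present-day (speciation, extinction, net diversification) rates."""
    lam = fit.params["lam0"]
    mu = fit.params["mu0"]
    return lam, mu, lam - mu
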