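"""Brownian-motion and early-burst models of continuous trait evolution.

Traits (e.g. seed mass in grams) are analysed on a log scale because they
span many orders of magnitude.  Both models are Gaussian, so given the
phylogenetic covariance matrix ``C`` the root state and rate have closed-form
ML estimates:

    z0 = (1' C^-1 x) / (1' C^-1 1)
    sigma2 = (x - z0)' C^-1 (x - z0) / n          (ML, n-denominator)

Under BM, ``C[i, j]`` is the shared root-to-MRCA path length.  Under the
early-burst (ACDC) model the instantaneous rate is
``sigma2_0 * exp(a * s)`` with ``s`` the time since the root, which on an
ultrametric tree rescales the covariance elementwise:

    C_EB = (exp(a * C_BM) - 1) / a

so the EB fit reduces to a 1-D optimisation over the exponent ``a`` with
``(sigma2_0, z0)`` profiled out analytically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = ["TraitFit", "log_transform", "fit_bm", "fit_eb", "select_trait_model"]

_MIN_TIPS = 4


@dataclass
class TraitFit:
    """One fitted trait-evolution model for a clade."""

    model: str               # "BM" or "EB"
    sigma2: float            # rate at the root (sigma2_0 for EB), per Myr
    a: float                 # EB exponent per Myr (0 for BM)
    z0: float                # root state, log-trait units
    loglik: float
    aic: float
    n: int                   # tips used
    converged: bool = True
    at_bound: bool = False

    @property
    def n_params(self) -> int:
        return 2 if self.model == "BM" else 3


def log_transform(values, base: float = 10.0) -> np.ndarray:
    """Elementwise logarithm of positive trait values."""
    x = np.asarray(list(values.values()) if hasattr(values, "values") else values,
                   dtype=float)
    if np.any(x <= 0):
        raise ValueError("trait values must be strictly positive for log transform")
    return np.log(x) / math.log(base)


def _align(tree: Phylogeny, x) -> tuple[np.ndarray, list[str]]:
    if hasattr(x, "keys"):
        labels = [t for t in tree.tip_labels if t in x]
        vals = np.asarray([float(x[t]) for t in labels])
    else:
        labels = list(tree.tip_labels)
        vals = np.asarray(x, dtype=float)
        if vals.size != len(labels):
            raise ValueError("trait vector length does not match tip count")
    return vals, labels


def _gaussian_profile(C: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Profile ML of (z0, sigma2) and the resulting log-likelihood."""
    n = x.size
    cf = cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    Cix = cho_solve(cf, x)
    z0 = float(ones @ Cix) / float(ones @ Ci1)
    resid = x - z0
    q = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sigma2 = q / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return z0, 0.0, math.inf  # degenerate: zero variance
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return z0, sigma2, ll


def fit_bm(tree: Phylogeny, x, min_tips: int = _MIN_TIPS) -> TraitFit:
    """Exact ML fit of single-rate Brownian motion.

    ``x`` may be a mapping from tip label to (log-scale) trait value or a
    vector aligned with ``tree.tip_labels``.
    """
    vals, labels = _align(tree, x)
    if vals.size < min_tips:
        raise ValueError(f"need >= {min_tips} tips with trait data, got {vals.size}")
    C = tree.vcv(labels)
    z0, sigma2, ll = _gaussian_profile(C, vals)
    if sigma2 == 0.0:
        logger.warning("zero trait variance: degenerate BM fit flagged")
        return TraitFit("BM", 0.0, 0.0, z0, -math.inf, math.inf, vals.size,
                        converged=False)
    return TraitFit("BM", sigma2, 0.0, z0, ll, 2 * 2 - 2 * ll, vals.size)


def fit_eb(
    tree: Phylogeny,
    x,
    min_tips: int = _MIN_TIPS,
    allow_accelerating: bool = False,
    bounds: tuple[float, float] | None = None,
) -> TraitFit:
    """ML fit of the early-burst / ACDC model.

    By default the exponent is constrained to deceleration,
    ``a in [-10 / depth, 0]``; ``allow_accelerating=True`` extends the upper
    bound to ``+10 / depth``.
    """
    vals, labels = _align(tree, x)
    if vals.size < min_tips:
        raise ValueError(f"need >= {min_tips} tips with trait data, got {vals.size}")
    C = tree.vcv(labels)
    depth = float(np.max(np.diag(C)))
    if bounds is None:
        lo = -10.0 / depth
        hi = 10.0 / depth if allow_accelerating else 0.0
    else:
        lo, hi = bounds

    def nll(a: float) -> float:
        if a == 0.0:
            Ca = C
        else:
            Ca = np.expm1(a * C) / a
        try:
            _, s2, ll = _gaussian_profile(Ca, vals)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    if lo == hi:
        a_hat = lo
    else:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        # the bounded minimiser never probes the exact endpoints; compare
        # a = 0 (the BM limit) explicitly so nesting holds to round-off
        a_hat = float(res.x)
        if hi >= 0.0 >= lo and nll(0.0) <= res.fun:
            a_hat = 0.0
    Ca = C if a_hat == 0.0 else np.expm1(a_hat * C) / a_hat
    z0, sigma2, ll = _gaussian_profile(Ca, vals)
    if sigma2 == 0.0:
        logger.warning("zero trait variance: degenerate EB fit flagged")
        return TraitFit("EB", 0.0, a_hat, z0, -math.inf, math.inf, vals.size,
                        converged=False)
    at_bound = math.isclose(a_hat, lo, abs_tol=1e-6) or (
        hi != 0.0 and math.isclose(a_hat, hi, abs_tol=1e-6)
    )
    return TraitFit("EB", sigma2, a_hat, z0, ll, 2 * 3 - 2 * ll, vals.size,
                    at_bound=at_bound)


def select_trait_model(fits) -> TraitFit:
    """Minimum-AIC fit; ties break toward the model with fewer parameters."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no successful trait-model fit to select from")
    if len(ok) < len(list(fits)):
        logger.info("selecting among %d of %d converged trait fits",
                    len(ok), len(list(fits)))
    return min(ok, key=lambda f: (f.aic, f.n_params))
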