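"""Correlation machinery linking macroevolutionary rates to traits.

Contains the structured rate-permutation (STRAPP-style) test over posterior
rate-shift configurations, Spearman correlation, phylogenetic generalised
least squares across clades, ordinary least squares, simulation-based
phylogenetic ANOVA, and reading/writing of BAMM-style event-data files.

A :class:`RegimeConfiguration` is one sample of a rate-shift configuration:
a partition of the tree's branches into regimes, each regime carrying a
speciation rate, an extinction rate and optionally a phenotypic rate.  The
structured permutation shuffles the regime-to-rate assignment uniformly
while keeping the shift locations fixed, which preserves the phylogenetic
autocorrelation of tip rates and yields the test's null distribution.

The permutation p-value follows the one-sided proportion rule: the fraction
of posterior samples in which the null correlation coefficient is greater
than the observed one.  Samples with a single regime are uninformative (the
permutation is the identity) and count toward the null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "RegimeConfiguration",
    "StrappResult",
    "PGLSResult",
    "spearman_rho",
    "strapp_test",
    "pgls_fit",
    "ols_fit",
    "phyl_anova",
    "read_event_csv",
    "write_event_csv",
]


# ----------------------------------------------------------------------
# regime configurations
# ----------------------------------------------------------------------
@dataclass
class RegimeConfiguration:
    """One rate-shift configuration on a phylogeny.

    ``tip_regime[i]`` is the regime index of the terminal branch of
    ``tree.tip_labels[i]``; ``lam``, ``mu`` and ``phen`` hold the per-regime
    rates.  ``regime_nodes`` holds the node at which each regime originates
    (index 0 is always the root regime) and ``edge_regime`` maps every node's
    parent edge to its regime, so branch-level statistics are available too.
    """

    tree: Phylogeny
    tip_regime: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    phen: np.ndarray | None = None
    regime_nodes: list = field(default_factory=list)
    edge_regime: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tip_regime = np.asarray(self.tip_regime, dtype=int)
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.phen is not None:
            self.phen = np.asarray(self.phen, dtype=float)
        if self.tip_regime.size != self.tree.n_tips:
            raise ValueError("tip_regime must cover every tip")
        if self.tip_regime.max() >= self.lam.size:
            raise ValueError("tip regime index out of range")

    @property
    def n_regimes(self) -> int:
        return int(self.lam.size)

    def _regime_values(self, parameter: str) -> np.ndarray:
        if parameter in ("lambda", "lam"):
            return self.lam
        if parameter == "mu":
            return self.mu
        if parameter in ("r", "netdiv"):
            return self.lam - self.mu
        if parameter in ("phen", "trait_rate"):
            if self.phen is None:
                raise ValueError("configuration carries no phenotypic rates")
            return self.phen
        raise ValueError(f"unknown parameter {parameter!r}")

    def tip_rates(self, parameter: str = "lambda",
                  permutation: np.ndarray | None = None) -> np.ndarray:
        """Per-tip rates; ``permutation`` reassigns rates among regimes."""
        vals = self._regime_values(parameter)
        if permutation is not None:
            vals = vals[permutation]
        return vals[self.tip_regime]

    def branch_rates(self, parameter: str = "lambda") -> np.ndarray:
        """Per-branch rates over all non-root edges (preorder)."""
        vals = self._regime_values(parameter)
        idx = [self.edge_regime[id(n)] for n in self.tree._tree.preorder_node_iter()
               if n.parent_node is not None]
        return vals[np.asarray(idx, dtype=int)]


def assign_regimes(tree: Phylogeny, shift_nodes: list) -> tuple[np.ndarray, dict, list]:
    """Partition branches by the nearest rootward shift.

    ``shift_nodes`` are the nodes (subtree roots) at which new regimes start;
    the root regime (index 0) is implicit.  Returns the per-tip regime index,
    a per-edge regime map keyed by ``id(node)`` and the regime-origin node
    list (root first).
    """
    regime_nodes = [tree.root] + [n for n in shift_nodes if n is not tree.root]
    index_of = {id(n): i for i, n in enumerate(regime_nodes)}
    edge_regime: dict[int, int] = {}
    tip_regime = np.zeros(tree.n_tips, dtype=int)
    tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}

    def walk(node, current: int) -> None:
        current = index_of.get(id(node), current)
        if node.parent_node is not None:
            edge_regime[id(node)] = current
        if node.is_leaf():
            tip_regime[tip_index[node.taxon.label]] = current
        for ch in node.child_nodes():
            walk(ch, current)

    walk(tree.root, 0)
    return tip_regime, edge_regime, regime_nodes


# ----------------------------------------------------------------------
# correlation statistics
# ----------------------------------------------------------------------
def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(scipy.stats.rankdata(x)) == 0 or np.ptp(scipy.stats.rankdata(y)) == 0:
        raise ValueError("zero variance in ranks: Spearman correlation undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class StrappResult:
    parameter: str
    obs_rho: np.ndarray
    null_rho: np.ndarray
    p_value: float
    n_samples: int
    seed: int | None

    @property
    def median_obs_rho(self) -> float:
        if np.all(np.isnan(self.obs_rho)):
            return math.nan
        return float(np.nanmedian(self.obs_rho))

    @property
    def abs_diffs(self) -> np.ndarray:
        """|observed - null| correlation differences across samples."""
        return np.abs(self.obs_rho - self.null_rho)


def strapp_test(
    posterior: list[RegimeConfiguration],
    tip_statistic,
    parameter: str = "lambda",
    seed: int | None = None,
    alternative: str = "greater",
) -> StrappResult:
    """Structured rate-permutation test of a tip statistic against rates.

    For every posterior sample the observed Spearman correlation between the
    per-tip macroevolutionary rate and ``tip_statistic`` is compared with the
    correlation after one uniform permutation of the regime-to-rate
    assignment (shift locations fixed).  The p-value is the proportion of
    samples whose null correlation exceeds the observed one
    (``alternative="greater"``); ``alternative="two-sided"`` compares
    absolute correlations instead.

    ``tip_statistic`` may be a mapping from tip label to value or a vector
    aligned with the tree's tip order; binary traits enter as 0/1.
    """
    if not posterior:
        raise ValueError("need at least one posterior sample")
    tree = posterior[0].tree
    if hasattr(tip_statistic, "keys"):
        missing = [t for t in tree.tip_labels if t not in tip_statistic]
        if missing:
            raise ValueError(f"tip_statistic missing tips: {missing[:5]}")
        stat = np.asarray([float(tip_statistic[t]) for t in tree.tip_labels])
    else:
        stat = np.asarray(tip_statistic, dtype=float)
        if stat.size != tree.n_tips:
            raise ValueError("tip_statistic length does not match tip count")
    rng = np.random.default_rng(seed)
    obs = np.empty(len(posterior))
    null = np.empty(len(posterior))
    exceed = np.zeros(len(posterior), dtype=bool)
    if all(cfg.n_regimes == 1 for cfg in posterior):
        logger.warning("every posterior sample has a single regime; "
                       "the structured permutation is the identity (p = 1)")
    for i, cfg in enumerate(posterior):
        if cfg.n_regimes == 1 or np.ptp(cfg.tip_rates(parameter)) == 0:
            # constant tip rates: the permutation is the identity and the
            # correlation undefined; the sample is uninformative
            obs[i] = null[i] = np.nan
            exceed[i] = True
            continue
        rates = cfg.tip_rates(parameter)
        obs[i] = spearman_rho(rates, stat)
        perm = rng.permutation(cfg.n_regimes)
        null[i] = spearman_rho(cfg.tip_rates(parameter, permutation=perm), stat)
        if alternative == "greater":
            exceed[i] = null[i] > obs[i]
        elif alternative == "two-sided":
            exceed[i] = abs(null[i]) > abs(obs[i])
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.mean(exceed))
    return StrappResult(parameter, obs, null, p, len(posterior), seed)


# ----------------------------------------------------------------------
# regressions
# ----------------------------------------------------------------------
@dataclass
class PGLSResult:
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    df: int
    sigma2: float
    n: int


def pgls_fit(y, x, tree: Phylogeny, labels=None) -> PGLSResult:
    """Phylogenetic GLS of ``y`` on ``x`` with Brownian covariance.

    ``tree`` holds one representative tip per observation; ``labels`` gives
    the tip order of ``y`` and ``x`` (default: the tree's tip order).  The
    error covariance is proportional to the BM variance-covariance matrix of
    the representative tree (Pagel's lambda fixed at 1); significance uses a
    t distribution with n - 2 degrees of freedom.
    """
    labels = list(labels) if labels is not None else list(tree.tip_labels)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n or len(labels) != n:
        raise ValueError("y, x and labels must have equal length")
    if n < 3:
        raise ValueError(f"need at least 3 observations for PGLS, got {n}")
    C = tree.vcv(labels)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular phylogenetic covariance: {exc}")
    X = np.column_stack([np.ones(n), x])
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df if df > 0 else 0.0
    cov = sigma2 * np.linalg.inv(XtX)
    se = math.sqrt(max(cov[1, 1], 0.0))
    if se > 0:
        t = float(beta[1]) / se
        p = 2.0 * scipy.stats.t.sf(abs(t), df)
    else:
        t, p = math.inf if beta[1] != 0 else 0.0, 0.0 if beta[1] != 0 else 1.0
    return PGLSResult(float(beta[1]), float(beta[0]), se, t, float(p), df,
                      sigma2, n)


@dataclass
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ols_fit(x, y) -> OLSResult:
    """Ordinary least squares of ``y`` on ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: OLS slope undefined")
    res = scipy.stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return OLSResult(float(res.slope), float(res.intercept), r2,
                     float(res.pvalue), x.size)


# ----------------------------------------------------------------------
# phylogenetic ANOVA
# ----------------------------------------------------------------------
def _f_statistics(data: np.ndarray, group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F for each row of ``data`` (vectorised)."""
    data = np.atleast_2d(data)
    m, n = data.shape
    grand = data.mean(axis=1, keepdims=True)
    ss_tot = np.sum((data - grand) ** 2, axis=1)
    ss_b = np.zeros(m)
    for g in range(n_groups):
        mask = group_idx == g
        ng = int(mask.sum())
        gm = data[:, mask].mean(axis=1)
        ss_b += ng * (gm - grand[:, 0]) ** 2
    ss_w = ss_tot - ss_b
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_b / df_b) / (ss_w / df_w)
    F[~np.isfinite(F)] = 0.0
    return F


def phyl_anova(
    tree: Phylogeny,
    groups,
    x,
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Phylogenetic ANOVA with a Brownian-simulation null.

    The observed one-way ANOVA F statistic of the tip values across groups
    is compared with F statistics from ``n_sim`` BM datasets simulated on
    the tree (rate estimated from the data); the p-value is the proportion
    of simulated F >= observed.
    """
    if hasattr(groups, "keys"):
        glabels = [groups[t] for t in tree.tip_labels]
    else:
        glabels = list(groups)
    if hasattr(x, "keys"):
        vals = np.asarray([float(x[t]) for t in tree.tip_labels])
    else:
        vals = np.asarray(x, dtype=float)
    if len(glabels) != tree.n_tips or vals.size != tree.n_tips:
        raise ValueError("groups and x must cover every tip")
    uniq = sorted(set(glabels))
    if len(uniq) < 2:
        raise ValueError("need at least two non-empty groups")
    gidx = np.asarray([uniq.index(g) for g in glabels])
    for g in range(len(uniq)):
        if not np.any(gidx == g):
            raise ValueError(f"group {uniq[g]!r} has no members")

    f_obs = float(_f_statistics(vals[None, :], gidx, len(uniq))[0])

    C = tree.vcv()
    # ML Brownian rate of the observed data (location does not affect F)
    ones = np.ones(tree.n_tips)
    Cinv_1 = np.linalg.solve(C, ones)
    Cinv_x = np.linalg.solve(C, vals)
    z0 = float(ones @ Cinv_x) / float(ones @ Cinv_1)
    resid = vals - z0
    sigma2 = float(resid @ np.linalg.solve(C, resid)) / tree.n_tips
    L = np.linalg.cholesky(C + 1e-12 * np.eye(tree.n_tips))
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, tree.n_tips)) @ (math.sqrt(max(sigma2, 0.0)) * L.T)
    f_null = _f_statistics(sims, gidx, len(uniq))
    p = float(np.mean(f_null >= f_obs))
    return f_obs, p


# ----------------------------------------------------------------------
# BAMM-style event-data I/O
# ----------------------------------------------------------------------
_EVENT_COLS = ["generation", "leftchild", "rightchild", "abstime",
               "lambdainit", "lambdashift", "muinit", "mushift"]


def attach_phenotypic_rates(
    posterior: list[RegimeConfiguration],
    phen_posterior: list[RegimeConfiguration],
) -> list[RegimeConfiguration]:
    """Attach per-regime phenotypic rates from a trait-run event posterior.

    The trait event file uses the single-rate dialect (rate in the
    ``lambdainit`` column).  Samples are matched positionally and must share
    the diversification posterior's regime structure.
    """
    if len(posterior) != len(phen_posterior):
        raise ValueError("posteriors have different numbers of samples")
    for cfg, pcfg in zip(posterior, phen_posterior):
        if not np.array_equal(cfg.tip_regime, pcfg.tip_regime):
            raise ValueError("trait posterior has a different shift "
                             "configuration than the diversification posterior")
        cfg.phen = pcfg.lam.copy()
    return posterior


def write_event_csv(posterior: list[RegimeConfiguration], path,
                    phen_posterior: bool = False) -> None:
    """Write a posterior of regime configurations as an event-data CSV.

    One row per regime per sample; the regime's origin node is encoded by a
    pair of descendant tip labels (``rightchild`` empty for a terminal
    branch), ``abstime`` is the origin's time since the root, and rates are
    constant within regimes (shift parameters written as 0).  With
    ``phen_posterior=True`` the phenotypic rate is written in the
    ``lambdainit`` column, matching the single-rate dialect of trait event
    files.
    """
    rows = []
    for gen, cfg in enumerate(posterior):
        depth = cfg.tree.depth
        for j, node in enumerate(cfg.regime_nodes):
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            left = leaves[0]
            right = leaves[-1] if len(leaves) > 1 else ""
            rate1 = (cfg.phen[j] if phen_posterior else cfg.lam[j])
            rows.append({
                "generation": gen,
                "leftchild": left,
                "rightchild": right,
                "abstime": depth - node.age,
                "lambdainit": rate1,
                "lambdashift": 0.0,
                "muinit": 0.0 if phen_posterior else cfg.mu[j],
                "mushift": 0.0,
            })
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False)


def read_event_csv(path, tree: Phylogeny) -> list[RegimeConfiguration]:
    """Read an event-data CSV into per-sample regime configurations.

    Rates that vary within a regime (nonzero shift parameters) are evaluated
    at the present day, matching the convention that tip rates are
    present-day rates.
    """
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} lacks columns: {missing}")
    tip_set = set(tree.tip_labels)
    out = []
    for gen, block in df.groupby("generation", sort=True):
        nodes, lam, mu = [], [], []
        root_first = []
        for _, row in block.iterrows():
            left = str(row["leftchild"])
            right = row["rightchild"]
            if left not in tip_set:
                raise ValueError(f"event file references unknown tip {left!r}")
            if pd.isna(right) or right == "":
                node = next(t for t in tree._tree.leaf_node_iter()
                            if t.taxon.label == left)
            else:
                if str(right) not in tip_set:
                    raise ValueError(f"event file references unknown tip {right!r}")
                node = tree._tree.mrca(taxon_labels=[left, str(right)])
            dt = tree.depth - float(row["abstime"])  # event -> present, Myr
            lam_now = float(row["lambdainit"]) * math.exp(float(row["lambdashift"]) * dt)
            mu_now = float(row["muinit"]) * math.exp(float(row["mushift"]) * dt)
            entry = (node, lam_now, mu_now)
            if node is tree.root:
                root_first.insert(0, entry)
            else:
                root_first.append(entry)
        if root_first[0][0] is not tree.root:
            raise ValueError(f"generation {gen}: no root event found")
        for node, l_, m_ in root_first:
            nodes.append(node); lam.append(l_); mu.append(m_)
        tip_regime, edge_regime, regime_nodes = assign_regimes(tree, nodes[1:])
        out.append(RegimeConfiguration(
            tree=tree, tip_regime=tip_regime, lam=np.asarray(lam),
            mu=np.asarray(mu), regime_nodes=regime_nodes,
            edge_regime=edge_regime,
        ))
    return out
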