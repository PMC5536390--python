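"""Synthetic trees, rate regimes, traits and sampling structure.

These generators emulate the statistical features of a large empirical
study system — an ultrametric timetree with genus-structured tips, a trait
spanning orders of magnitude evolving by (possibly regime-specific)
Brownian motion on the log scale, rate-shift configurations resembling a
posterior sample set, and taxonomically non-random incomplete sampling —
so that every pipeline stage can be exercised and calibrated without
external data.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .comparative import RegimeConfiguration, assign_regimes, write_event_csv
from .phylo import GenusRichnessTable, Phylogeny, TraitTable

__all__ = [
    "simulate_bd_tree",
    "simulate_regimes",
    "simulate_bm_traits",
    "make_taxonomy_and_subsample",
    "make_synthetic_posterior",
    "generate_study_fixture",
    "StudyFixture",
]


# ----------------------------------------------------------------------
# birth-death tree simulation
# ----------------------------------------------------------------------
class _Lineage:
    __slots__ = ("parent", "start", "end", "children")

    def __init__(self, parent, start):
        self.parent = parent
        self.start = start
        self.end = None       # None while extant
        self.children = []


def _gillespie_crown(rng: np.random.Generator, lam: float, mu: float,
                     n_tips: int | None, t_max: float | None):
    """Forward crown simulation; returns (root lineages, end time, n extant)."""
    roots = [_Lineage(None, 0.0), _Lineage(None, 0.0)]
    active = list(roots)
    t = 0.0
    while True:
        n = len(active)
        if n == 0:
            return roots, t, 0
        total = n * (lam + mu)
        wait = rng.exponential(1.0 / total)
        if t_max is not None and t + wait > t_max:
            t = t_max
            break
        t += wait
        i = rng.integers(n)
        lin = active[i]
        if rng.random() < lam / (lam + mu):
            lin.end = t
            lin.children = [_Lineage(lin, t), _Lineage(lin, t)]
            active.pop(i)
            active.extend(lin.children)
            if n_tips is not None and len(active) == n_tips:
                # run to just before the next event so tips get length
                t += rng.exponential(1.0 / (len(active) * (lam + mu)))
                break
        else:
            lin.end = t
            active.pop(i)
    for lin in active:
        lin.end = t
    return roots, t, len(active)


def _prune_newick(lin: _Lineage, t_end: float, counter) -> tuple[str, float] | None:
    """Newick of the extant part below ``lin``; None if fully extinct."""
    length = lin.end - lin.start
    if not lin.children:
        if lin.end < t_end:  # extinct
            return None
        counter[0] += 1
        return f"T{counter[0]}", length
    kept = [s for s in (_prune_newick(c, t_end, counter) for c in lin.children)
            if s is not None]
    if not kept:
        return None
    if len(kept) == 1:  # suppress unifurcation
        text, sub_len = kept[0]
        return text, sub_len + length
    body = ",".join(f"{txt}:{ln:.10f}" for txt, ln in kept)
    return f"({body})", length


def simulate_bd_tree(
    lam: float,
    mu: float = 0.0,
    n_tips: int | None = None,
    t_max: float | None = None,
    seed: int | None = None,
    max_retries: int = 1000,
) -> Phylogeny:
    """Simulate a reconstructed (extant-only) crown birth-death tree.

    Exactly one of ``n_tips`` and ``t_max`` must be given.  Simulation
    starts from the two crown lineages; runs going extinct (or, under the
    tip-count stop, failing to reach the target) are resimulated, so the
    output is conditioned on survival.  Extinct lineages are pruned and
    unifurcations suppressed; tips are labelled ``T1..Tn``.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if (n_tips is None) == (t_max is None):
        raise ValueError("specify exactly one of n_tips or t_max")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        roots, t_end, n_extant = _gillespie_crown(rng, lam, mu, n_tips, t_max)
        if n_extant < 2:
            continue
        if n_tips is not None and n_extant != n_tips:
            continue
        counter = [0]
        kept = [s for s in (_prune_newick(r, t_end, counter) for r in roots)
                if s is not None]
        if len(kept) == 2:
            body = ",".join(f"{txt}:{ln:.10f}" for txt, ln in kept)
            text = f"({body});"
        else:  # one crown lineage fully extinct: younger crown, drop stem
            text = f"{kept[0][0]};" if kept[0][0].startswith("(") else None
            if text is None:
                continue  # a single surviving tip is not a tree
        tree = Phylogeny.from_newick(text, strict=True, rtol=1e-4)
        if tree.n_tips >= 2:
            return tree
    raise RuntimeError(
        f"no surviving tree in {max_retries} attempts (lam={lam}, mu={mu})"
    )


# ----------------------------------------------------------------------
# regimes
# ----------------------------------------------------------------------
def simulate_regimes(
    tree: Phylogeny,
    n_shifts: int,
    rate_priors: dict | None = None,
    min_regime_tips: int = 5,
    seed: int | None = None,
) -> RegimeConfiguration:
    """Place rate shifts on branches and draw per-regime rates.

    Shift locations are drawn without replacement with probability
    proportional to branch length among edges subtending at least
    ``min_regime_tips`` tips (a shift affecting only one or two tips carries
    no detectable signal and would not appear in a credible shift
    configuration); a shifted branch and everything below it (until a nested
    shift) forms one regime.  Per-regime speciation is drawn log-uniformly
    on ``lam_range``, extinction as ``lam * U(mu_frac_range)`` and the
    phenotypic rate log-uniformly on ``phen_range``.
    """
    priors = {
        "lam_range": (0.05, 0.5),
        "mu_frac_range": (0.0, 0.8),
        "phen_range": (0.05, 5.0),
    }
    if rate_priors:
        priors.update(rate_priors)
    rng = np.random.default_rng(seed)
    edges = [n for n in tree._tree.preorder_node_iter()
             if n.parent_node is not None
             and sum(1 for _ in n.leaf_iter()) >= min_regime_tips]
    if n_shifts < 0 or n_shifts > len(edges):
        raise ValueError(
            f"n_shifts must be in 0..{len(edges)} (edges with >= "
            f"{min_regime_tips} tips), got {n_shifts}")
    lengths = np.asarray([e.edge.length for e in edges], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(edges), size=n_shifts, replace=False, p=probs)
    shift_nodes = [edges[i] for i in idx]
    tip_regime, edge_regime, regime_nodes = assign_regimes(tree, shift_nodes)
    n_reg = len(regime_nodes)
    lo, hi = priors["lam_range"]
    lam = np.exp(rng.uniform(math.log(lo), math.log(hi), n_reg))
    mu = lam * rng.uniform(*priors["mu_frac_range"], n_reg)
    plo, phi = priors["phen_range"]
    phen = np.exp(rng.uniform(math.log(plo), math.log(phi), n_reg))
    return RegimeConfiguration(tree=tree, tip_regime=tip_regime, lam=lam, mu=mu,
                               phen=phen, regime_nodes=regime_nodes,
                               edge_regime=edge_regime)


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------
def simulate_bm_traits(
    tree: Phylogeny,
    sigma2,
    z0: float = 0.0,
    regimes: RegimeConfiguration | None = None,
    seed: int | None = None,
    as_raw: bool = False,
    log_base: float = 10.0,
) -> TraitTable | dict[str, float]:
    """Simulate Brownian trait values along the tree.

    ``sigma2`` is either a single rate or, with ``regimes`` given, ignored in
    favour of the configuration's per-regime phenotypic rates.  Values are
    simulated on the log scale; ``as_raw=True`` returns a
    :class:`TraitTable` of back-transformed positive values (raw seed masses
    spanning orders of magnitude), otherwise a label -> log-value dict.
    """
    rng = np.random.default_rng(seed)
    if regimes is not None and regimes.phen is None:
        raise ValueError("regime configuration carries no phenotypic rates")
    out: dict[str, float] = {}

    def rate_of(node) -> float:
        if regimes is None:
            return float(sigma2)
        return float(regimes.phen[regimes.edge_regime[id(node)]])

    def walk(node, value: float) -> None:
        if node.parent_node is not None:
            s2 = rate_of(node)
            bl = node.edge.length or 0.0
            if s2 > 0 and bl > 0:
                value = value + rng.normal(0.0, math.sqrt(s2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = value
        for ch in node.child_nodes():
            walk(ch, value)

    walk(tree.root, float(z0))
    if as_raw:
        return TraitTable({k: float(log_base) ** v for k, v in out.items()})
    return out


# ----------------------------------------------------------------------
# taxonomy emulation and subsampling
# ----------------------------------------------------------------------
def make_taxonomy_and_subsample(
    tree: Phylogeny,
    n_genera: int,
    skew: float = 1.0,
    sampling_fractions=1.0,
    seed: int | None = None,
    max_retries: int = 100,
) -> tuple[Phylogeny, GenusRichnessTable, dict[str, str]]:
    """Assign genera as contiguous tip blocks and subsample tips.

    Tips in tree (ladderised traversal) order are partitioned into
    ``n_genera`` contiguous blocks whose sizes follow a symmetric Dirichlet
    with concentration ``1/skew`` (larger ``skew`` -> more uneven genera,
    emulating the long-tailed genus-size distribution of real taxonomies).
    Each tip is retained independently with its genus's sampling fraction
    (scalar, or a sequence of per-genus fractions cycled over genera).
    Returns the pruned tree with ``Genus_species`` labels, a richness table
    with the pre-pruning block sizes as described richness, and the
    old-label -> new-label map.
    """
    if not (1 <= n_genera <= tree.n_tips):
        raise ValueError(f"n_genera must be in 1..{tree.n_tips}")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(n_genera, 1.0 / max(skew, 1e-6)))
    sizes = np.maximum(1, np.round(weights * tree.n_tips).astype(int))
    while sizes.sum() > tree.n_tips:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < tree.n_tips:
        sizes[np.argmin(sizes)] += 1
    fr = np.resize(np.asarray(sampling_fractions, dtype=float), n_genera)
    if np.any((fr <= 0) | (fr > 1)):
        raise ValueError("sampling fractions must be in (0, 1]")
    rename: dict[str, str] = {}
    genus_of: dict[str, int] = {}
    pos = 0
    for g, size in enumerate(sizes):
        for j in range(size):
            old = tree.tip_labels[pos]
            rename[old] = f"G{g + 1}_sp{j + 1}"
            genus_of[old] = g
            pos += 1
    richness = GenusRichnessTable(
        {f"G{g + 1}": int(s) for g, s in enumerate(sizes)}
    )
    for _ in range(max_retries):
        keep = [old for old in tree.tip_labels
                if rng.random() < fr[genus_of[old]]]
        if len(keep) >= 2:
            break
    else:
        raise RuntimeError("subsampling left fewer than 2 tips")
    pruned = tree.prune_to(keep)
    text = pruned.to_newick()
    for old in sorted(rename, key=len, reverse=True):
        text = text.replace(old, rename[old])
    return (Phylogeny.from_newick(text, strict=False), richness,
            {o: rename[o] for o in keep})


# ----------------------------------------------------------------------
# synthetic posterior
# ----------------------------------------------------------------------
def make_synthetic_posterior(
    base: RegimeConfiguration,
    n_samples: int,
    jitter: float = 0.1,
    relocate_frac: float = 0.0,
    seed: int | None = None,
) -> list[RegimeConfiguration]:
    """Emulate a posterior sample set around a base configuration.

    Each sample multiplies every regime rate by an independent lognormal
    factor with log-sd ``jitter`` (so the rate coefficient of variation is
    about ``jitter``) and, with probability ``relocate_frac`` per shift,
    moves a shift to a random branch of the subtree it governs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        nodes = list(base.regime_nodes)
        moved = False
        for i in range(1, len(nodes)):
            if relocate_frac > 0 and rng.random() < relocate_frac:
                cand = [n for n in nodes[i].preorder_iter()
                        if n.parent_node is not None]
                nodes[i] = cand[rng.integers(len(cand))]
                moved = True
        if moved:
            tip_regime, edge_regime, regime_nodes = assign_regimes(
                base.tree, nodes[1:])
        else:
            tip_regime, edge_regime, regime_nodes = (
                base.tip_regime, base.edge_regime, base.regime_nodes)
        n_reg = len(regime_nodes)
        factor = np.exp(rng.normal(0.0, jitter, (3, n_reg))) if jitter > 0 \
            else np.ones((3, n_reg))
        out.append(RegimeConfiguration(
            tree=base.tree,
            tip_regime=tip_regime,
            lam=base.lam * factor[0],
            mu=base.mu * factor[1],
            phen=None if base.phen is None else base.phen * factor[2],
            regime_nodes=regime_nodes,
            edge_regime=edge_regime,
        ))
    return out


# ----------------------------------------------------------------------
# whole-study fixture
# ----------------------------------------------------------------------
@dataclass
class StudyFixture:
    """A coherent synthetic study: tree, traits, taxonomy and posterior."""

    tree: Phylogeny
    traits: TraitTable
    richness: GenusRichnessTable
    posterior: list[RegimeConfiguration]
    base_config: RegimeConfiguration
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        pd.DataFrame(
            {"species": list(self.traits.values),
             "value": list(self.traits.values.values())}
        ).to_csv(outdir / "traits.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"genus": list(self.richness.counts),
             "n_described": list(self.richness.counts.values())}
        ).to_csv(outdir / "richness.tsv", sep="\t", index=False)
        write_event_csv(self.posterior, outdir / "posterior.csv")
        if self.posterior and self.posterior[0].phen is not None:
            write_event_csv(self.posterior, outdir / "posterior_phen.csv",
                            phen_posterior=True)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


def generate_study_fixture(
    seed: int,
    n_tips: int = 300,
    n_shifts: int = 3,
    coupling: float = 0.0,
    coupling_power: float = 1.0,
    lam: float = 0.15,
    mu: float = 0.05,
    n_genera: int = 40,
    genus_skew: float = 2.0,
    sampling_range: tuple[float, float] = (0.5, 1.0),
    n_posterior: int = 50,
    jitter: float = 0.1,
    base_phen: float = 0.5,
) -> StudyFixture:
    """One call producing a small coherent synthetic study.

    ``coupling`` sets the strength of the trait-rate/speciation association:
    regime phenotypic rates are ``base_phen * (lam_regime / mean_lam) **
    (coupling * coupling_power)``, so ``coupling = 0`` yields a null dataset
    and larger values a detectable positive association.  Trait values are
    simulated with the per-regime rates and returned as raw (back-
    transformed) masses; ``truth`` records everything needed for recovery
    tests.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=6)
    full = simulate_bd_tree(lam, mu, n_tips=n_tips, seed=int(sub_seeds[0]))
    fr = rng.uniform(*sampling_range, size=n_genera)
    tree, richness, rename = make_taxonomy_and_subsample(
        full, n_genera=n_genera, skew=genus_skew, sampling_fractions=fr,
        seed=int(sub_seeds[1]))
    base = simulate_regimes(tree, n_shifts=n_shifts, seed=int(sub_seeds[2]))
    rel = base.lam / base.lam.mean()
    base.phen = base_phen * rel ** (coupling * coupling_power)
    traits = simulate_bm_traits(tree, sigma2=None, regimes=base, z0=0.0,
                                seed=int(sub_seeds[3]), as_raw=True)
    posterior = make_synthetic_posterior(base, n_posterior, jitter=jitter,
                                         seed=int(sub_seeds[4]))
    truth = {
        "seed": int(seed),
        "coupling": float(coupling),
        "lam_true": [float(v) for v in base.lam],
        "mu_true": [float(v) for v in base.mu],
        "phen_true": [float(v) for v in base.phen],
        "n_regimes": base.n_regimes,
        "n_tips": tree.n_tips,
    }
    return StudyFixture(tree=tree, traits=traits, richness=richness,
                        posterior=posterior, base_config=base, truth=truth)
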