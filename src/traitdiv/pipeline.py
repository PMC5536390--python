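"""End-to-end orchestration of the two analysis arms.

* The clade arm: time-sliced clade extraction, sampling-fraction and
  crown-capture filters, method-of-moments and six-model ML diversification
  estimates, BM/EB trait-rate estimates, and across-clade PGLS of log trait
  rate (and root trait state) against log present-day speciation, per slice.

* The permutation arm: STRAPP-style structured permutation tests of tip
  trait values and tip phenotypic rates against speciation, extinction and
  net diversification over a posterior of rate-shift configurations, plus
  the neutral-trait type-I-error experiment.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, diversification, traits as trait_models
from .phylo import (GenusRichnessTable, Phylogeny, TraitTable, annotate_clades,
                    filter_clades, slice_clades)
from .simulate import simulate_bm_traits

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_clade_analysis", "run_strapp_analysis",
           "run_type1_experiment"]


@dataclass
class AnalysisConfig:
    """Tunable settings of the analysis pipeline."""

    slice_width: float = 2.0
    max_age: float = 20.0
    min_tips: int = 4
    min_f: float = 0.3
    min_p_crown: float = 0.7
    eps_values: tuple[float, ...] = (0.0, 0.5, 0.9)
    eps_headline: float = 0.5
    congeneric_only: bool = False
    fit_ml_models: bool = True
    lambda_source: str = "ml"           # "ml" (best-AIC present-day) or "mom"
    trait_log_base: float = 10.0
    allow_accelerating_eb: bool = False
    net_div_pgls: bool = False
    alpha_level: float = 0.05
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_f <= 1 and 0 <= self.min_p_crown <= 1):
            raise ValueError("filter thresholds out of range")
        if self.lambda_source not in ("ml", "mom"):
            raise ValueError("lambda_source must be 'ml' or 'mom'")
        for e in self.eps_values:
            if not (0 <= e < 1):
                raise ValueError("relative extinction fractions must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "eps_values" in data:
            data["eps_values"] = tuple(data["eps_values"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["eps_values"] = list(d["eps_values"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _eps_col(eps: float) -> str:
    return f"r_mom_eps{eps:g}".replace(".", "p")


def clade_table(
    tree: Phylogeny,
    traits: TraitTable,
    richness: GenusRichnessTable,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Extract, filter and analyse clades; one row per retained clade."""
    clades = slice_clades(tree, config.slice_width, config.max_age,
                          config.min_tips)
    annotate_clades(tree, clades, richness)
    clades = filter_clades(clades, config.min_f, config.min_p_crown)
    if config.congeneric_only:
        clades = [c for c in clades
                  if len({tree.genus_of(t) for t in c.tips}) == 1]
    log_traits = traits.log_values(config.trait_log_base)
    rows = []
    for rec in clades:
        row: dict = {
            "clade_id": rec.clade_id, "slice": rec.slice_index,
            "crown_age": rec.crown_age, "k": rec.k, "n": rec.n,
            "f": rec.f, "p_crown": rec.p_crown,
        }
        for eps in config.eps_values:
            row[_eps_col(eps)] = diversification.mom_diversification(
                rec.crown_age, rec.n, eps)
        row["lambda_mom"] = (row[_eps_col(config.eps_headline)]
                             / (1.0 - config.eps_headline))
        sub = tree.extract_clade(rec.crown_node)
        if config.fit_ml_models:
            try:
                fits = diversification.fit_bd_models(
                    sub, f=rec.f, n_restarts=config.n_restarts,
                    min_tips=config.min_tips, seed=config.seed)
                best = fits[0]
                lam0, mu0, r0 = diversification.present_rates(best)
                row.update(best_model=best.model, lam0=best.params["lam0"],
                           alpha=best.params["alpha"], mu0=best.params["mu0"],
                           beta=best.params["beta"], lambda_ml=lam0,
                           r_ml=r0, div_loglik=best.loglik, div_aic=best.aic)
            except RuntimeError as exc:
                logger.warning("clade %s: %s", rec.clade_id, exc)
                row.update(best_model="NA")
        clade_traits = {t: log_traits[t] for t in rec.tips if t in log_traits}
        if len(clade_traits) >= config.min_tips:
            sub_tr = sub.prune_to(clade_traits) if len(clade_traits) < sub.n_tips else sub
            try:
                bm = trait_models.fit_bm(sub_tr, clade_traits,
                                         min_tips=config.min_tips)
                eb = trait_models.fit_eb(
                    sub_tr, clade_traits, min_tips=config.min_tips,
                    allow_accelerating=config.allow_accelerating_eb)
                best_tr = trait_models.select_trait_model([bm, eb])
                row.update(k_trait=best_tr.n, trait_model=best_tr.model,
                           sigma2=best_tr.sigma2, eb_a=best_tr.a,
                           z0=best_tr.z0, trait_loglik=best_tr.loglik,
                           trait_aic=best_tr.aic)
            except ValueError as exc:
                logger.warning("clade %s trait fit: %s", rec.clade_id, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _slice_pgls(table: pd.DataFrame, tree: Phylogeny, clades_by_id: dict,
                ycol: str, xcol: str) -> dict | None:
    sub = table.dropna(subset=[ycol, xcol])
    sub = sub[sub[xcol] > 0]  # rates enter the regression on the log scale
    if ycol == "sigma2":
        sub = sub[sub[ycol] > 0]
    if len(sub) < 3:
        return None
    reps = [clades_by_id[cid].tips[0] for cid in sub["clade_id"]]
    rep_tree = tree.prune_to(reps)
    y = sub[ycol].to_numpy(dtype=float)
    x = np.log(sub[xcol].to_numpy(dtype=float))
    if ycol == "sigma2":
        y = np.log(y)
    try:
        res = comparative.pgls_fit(y, x, rep_tree, labels=reps)
    except np.linalg.LinAlgError as exc:
        logger.warning("PGLS failed: %s", exc)
        return None
    return {"n_clades": len(sub), "slope": res.slope, "se": res.slope_se,
            "t": res.t_stat, "p": res.p_value}


def run_clade_analysis(
    tree: Phylogeny,
    traits: TraitTable,
    richness: GenusRichnessTable,
    config: AnalysisConfig | None = None,
    outdir=None,
) -> dict:
    """Run the clade arm; returns the clade table and per-slice PGLS slopes.

    For each time slice with at least three analysable clades, two PGLS
    regressions are fitted: log trait rate (best-model sigma^2) against log
    present-day speciation, and root trait state against log speciation.
    Net-diversification variants are added when ``config.net_div_pgls``.
    """
    config = config or AnalysisConfig()
    missing = sorted({tree.genus_of(t) for t in tree.tip_labels}
                     - set(richness.counts))
    if missing:
        raise KeyError(f"genera missing from richness table: {missing}")
    table = clade_table(tree, traits, richness, config)
    clades = slice_clades(tree, config.slice_width, config.max_age,
                          config.min_tips)
    clades_by_id = {c.clade_id: c for c in clades}
    xcol = "lambda_ml" if config.lambda_source == "ml" else "lambda_mom"
    summary_rows = []
    if len(table):
        for s, sl_table in table.groupby("slice"):
            pairs = [("sigma2", xcol, "trait_rate_vs_lambda"),
                     ("z0", xcol, "trait_vs_lambda")]
            if config.net_div_pgls:
                rcol = "r_ml" if config.lambda_source == "ml" else \
                    _eps_col(config.eps_headline)
                pairs += [("sigma2", rcol, "trait_rate_vs_r")]
            for ycol, xc, name in pairs:
                if xc not in sl_table.columns or ycol not in sl_table.columns:
                    continue
                res = _slice_pgls(sl_table, tree, clades_by_id, ycol, xc)
                if res is None:
                    logger.warning("slice %d: fewer than 3 clades for %s; "
                                   "PGLS skipped", s, name)
                    continue
                summary_rows.append({"slice": s, "test": name, **res})
    summary = pd.DataFrame(summary_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        if len(table):
            for s, sl_table in table.groupby("slice"):
                sl_table.to_csv(outdir / f"clades_slice{s}.tsv", sep="\t",
                                index=False, na_rep="NA")
        summary.to_csv(outdir / "pgls_summary.tsv", sep="\t", index=False,
                       na_rep="NA")
    return {"clades": table, "pgls": summary}


def run_strapp_analysis(
    posterior,
    traits: TraitTable,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    outdir=None,
) -> pd.DataFrame:
    """Run the six permutation tests: {lambda, mu, r} x {trait, trait rate}.

    The tip trait statistic is the log trait value; the tip trait-rate
    statistic is the per-tip phenotypic rate averaged over the posterior.
    """
    config = config or AnalysisConfig()
    if not posterior:
        raise ValueError("empty posterior")
    tree = posterior[0].tree
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise ValueError(f"trait table missing tree tips: {missing[:5]}")
    log_traits = traits.log_values(config.trait_log_base)
    stats = {"trait": np.asarray([log_traits[t] for t in tree.tip_labels])}
    if posterior[0].phen is not None:
        stats["trait_rate"] = np.mean(
            [cfg.tip_rates("phen") for cfg in posterior], axis=0)
    seed = config.seed if seed is None else seed
    rows, results = [], {}
    for j, (sname, stat) in enumerate(stats.items()):
        for i, param in enumerate(("lambda", "mu", "r")):
            res = comparative.strapp_test(posterior, stat, parameter=param,
                                          seed=seed + 13 * i + 101 * j)
            results[(param, sname)] = res
            rows.append({"parameter": param, "statistic": sname,
                         "median_rho": res.median_obs_rho,
                         "p": res.p_value, "n_samples": res.n_samples,
                         "seed": res.seed})
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "strapp_results.tsv", sep="\t", index=False)
        dist = pd.DataFrame({
            f"{p}_{s}_absdiff": results[(p, s)].abs_diffs
            for (p, s) in results})
        dist.to_csv(outdir / "strapp_null_differences.tsv", sep="\t",
                    index=False)
    return df


def run_type1_experiment(
    tree: Phylogeny,
    posterior,
    n_datasets: int = 200,
    sigma2: float = 1.0,
    parameter: str = "lambda",
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Neutral-trait calibration of the structured permutation test.

    Simulates ``n_datasets`` single-rate BM traits on the tree (independent
    of the rate regimes), runs the permutation test of each against the
    chosen macroevolutionary parameter, and reports the fraction of
    datasets significant at ``alpha`` with its binomial standard error.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        trait = simulate_bm_traits(tree, sigma2=sigma2,
                                   seed=int(rng.integers(2**31 - 1)))
        res = comparative.strapp_test(
            posterior, trait, parameter=parameter,
            seed=int(rng.integers(2**31 - 1)))
        pvals[i] = res.p_value
    hits = int(np.sum(pvals < alpha))
    est = hits / n_datasets
    se = (math.sqrt(est * (1 - est) / n_datasets) if n_datasets > 1
          else math.nan)
    return {"type1": est, "se": se, "n_datasets": n_datasets,
            "alpha": alpha, "p_values": pvals}
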