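"""Simulation studies: polygenic score behaviour under the two models.

Study 1 (causal variants known): simulate phenotypes under the local and
global models on a synthetic admixed cohort and score individuals with
TotPGS/ParPGS built from the European causal effects, summarising squared
score-phenotype correlations per global-ancestry subgroup.

Study 2 (tagging variants): phenotypes are still generated from causal
variants, but scores use tagging variants whose European effect sizes are
derived from allele frequencies and LD estimated on a separate homogeneous
European reference panel — emulating the realistic setting where only
GWAS-ascertained proxies of causal variants are available.

The distinguishability grid applies two-sided Wilcoxon rank-sum tests to
the per-draw squared correlations of the two models at each (rho, r2) bin,
recording the proportion of significant comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cs
from . import effects as ef
from .ancestry_stats import conditional_allele_frequencies, estimate_ld
from .phenosim import demean_haplotypes
from .theory import TheoryInputs, predict

__all__ = [
    "ExperimentConfig",
    "SimulatedCohort",
    "build_cohort",
    "simulate_r2_draws",
    "run_sim_study1",
    "run_sim_study2",
    "distinguishability_grid",
    "null_rejection_rate",
    "compare_to_theory",
]


@dataclass
class ExperimentConfig:
    """Configuration for the simulation studies (scaled-down defaults)."""

    n: int = 2000
    p: int = 1000
    n_seeds: int = 5
    n_draws: int = 100
    rho_grid: tuple = (0.2, 0.5, 0.9, 1.0)
    r2_grid: tuple = (0.1, 0.4)
    scenario: str = "causal_known"  # causal_known | tagging
    alpha: float = 0.01
    master_seed: int = 0
    n_groups: int = 4
    fst: float = 0.15
    beta_shape: tuple = cs.DEFAULT_BETA_SHAPE
    freq_source: str = "sample_conditional"
    # tagging-scenario knobs
    n_eur_panel: int = 5000
    lambda_eur_range: tuple = (0.9, 0.995)
    ld_discordance: float = 0.5
    tag_freq_jitter: float = 0.02

    def __post_init__(self):
        if not self.rho_grid or not self.r2_grid:
            raise ValueError("parameter grids must be non-empty")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.scenario not in ("causal_known", "tagging"):
            raise ValueError("scenario must be 'causal_known' or 'tagging'")


@dataclass
class SimulatedCohort:
    """A realized synthetic cohort with precomputed score ingredients."""

    la: cs.LocalAncestryPanel
    global_ancestry: cs.GlobalAncestryVector
    groups: cs.SubgroupAssignment
    causal_freqs: cs.AncestryFrequencies
    causal: cs.HaplotypePanel
    causal_sums: dict  # (n, p) demeaned-dosage sums: total / eur / afr
    tagging: Optional[cs.HaplotypePanel] = None
    tagging_freqs: Optional[cs.AncestryFrequencies] = None
    tagging_sums: Optional[dict] = None
    pair_map: Optional[cs.LinkedPairMap] = None
    theta_eur_hat: Optional[np.ndarray] = None  # EUR-panel plug-in scaling

    @property
    def abar(self) -> np.ndarray:
        return self.global_ancestry.values


def build_cohort(
    cfg: ExperimentConfig,
    rng: np.random.Generator,
    tagging: bool | None = None,
    global_ancestry: cs.GlobalAncestryVector | None = None,
) -> SimulatedCohort:
    """Generate one cohort replicate according to the configuration."""
    tagging = cfg.scenario == "tagging" if tagging is None else tagging
    if global_ancestry is None:
        global_ancestry = cs.sample_global_ancestry(cfg.n, cfg.beta_shape, seed=rng)
    la = cs.sample_local_ancestry(global_ancestry, cfg.p, mode="independent", seed=rng)
    groups = cs.split_subgroups(global_ancestry, cfg.n_groups)
    causal_freqs = cs.sample_ancestral_frequencies(
        cfg.p, fst=cfg.fst, seed=rng, role="causal"
    )

    if not tagging:
        causal = cs.sample_haplotypes(la, causal_freqs, seed=rng)
        xhat = demean_haplotypes(causal, la, causal_freqs, cfg.freq_source)
        return SimulatedCohort(
            la=la,
            global_ancestry=global_ancestry,
            groups=groups,
            causal_freqs=causal_freqs,
            causal=causal,
            causal_sums=xhat.haplotype_sums(la),
        )

    # Tagging variants: frequencies drawn from the same ancestral frequency
    # per pair so causal and tagging marginals resemble variants in high LD.
    jitter = cfg.tag_freq_jitter
    tagging_freqs = cs.AncestryFrequencies(
        f_afr=np.clip(
            causal_freqs.f_afr + rng.normal(0, jitter, cfg.p), 0.01, 0.99
        ),
        f_eur=np.clip(
            causal_freqs.f_eur + rng.normal(0, jitter, cfg.p), 0.01, 0.99
        ),
        role="tagging",
    )
    lam_eur = rng.uniform(*cfg.lambda_eur_range, size=cfg.p)
    lam_afr = lam_eur * (1.0 - rng.uniform(0.0, cfg.ld_discordance, size=cfg.p))
    lam_eur = _clip_feasible(lam_eur, causal_freqs.f_eur, tagging_freqs.f_eur)
    lam_afr = _clip_feasible(lam_afr, causal_freqs.f_afr, tagging_freqs.f_afr)

    causal, tag_panel, pair_map = cs.sample_linked_pairs(
        causal_freqs, tagging_freqs, lam_afr, lam_eur, la, seed=rng
    )
    xhat_c = demean_haplotypes(causal, la, causal_freqs, cfg.freq_source)
    xhat_t = demean_haplotypes(tag_panel, la, tagging_freqs, cfg.freq_source)

    # Homogeneous European reference panel for plug-in frequency and LD
    # estimates used to derive European tagging effect sizes.
    eur_global = cs.GlobalAncestryVector(np.zeros(cfg.n_eur_panel))
    eur_la = cs.LocalAncestryPanel(
        np.zeros((cfg.n_eur_panel, cfg.p, 2), dtype=np.int8),
        global_ancestry=eur_global,
    )
    eur_causal, eur_tag, _ = cs.sample_linked_pairs(
        causal_freqs, tagging_freqs, lam_afr, lam_eur, eur_la, seed=rng
    )
    f_hat = conditional_allele_frequencies(eur_causal, eur_la)
    ft_hat = conditional_allele_frequencies(eur_tag, eur_la)
    lam_hat = estimate_ld(eur_causal, eur_tag, eur_la, "eur")
    fc, ft = np.clip(f_hat.f_eur, 0.01, 0.99), np.clip(ft_hat.f_eur, 0.01, 0.99)
    theta_eur_hat = lam_hat * np.sqrt(fc * (1 - fc) / (ft * (1 - ft)))

    return SimulatedCohort(
        la=la,
        global_ancestry=global_ancestry,
        groups=groups,
        causal_freqs=causal_freqs,
        causal=causal,
        causal_sums=xhat_c.haplotype_sums(la),
        tagging=tag_panel,
        tagging_freqs=tagging_freqs,
        tagging_sums=xhat_t.haplotype_sums(la),
        pair_map=pair_map,
        theta_eur_hat=theta_eur_hat,
    )


def _clip_feasible(lam, fc, ft):
    """Clip LD targets to the Frechet-feasible range for the marginals."""
    denom = np.sqrt(fc * (1 - fc) * ft * (1 - ft))
    lam_max = (np.minimum(fc, ft) - fc * ft) / denom
    lam_min = (np.maximum(0.0, fc + ft - 1.0) - fc * ft) / denom
    return np.clip(lam, lam_min, lam_max)


def _column_r2(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of matching columns of (n, B) arrays."""
    sc = s - s.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = np.sum(sc * yc, axis=0)
    den = np.sum(sc**2, axis=0) * np.sum(yc**2, axis=0)
    return num**2 / den


def simulate_r2_draws(
    cohort: SimulatedCohort,
    cov: ef.BaseCovariance,
    model: str,
    n_draws: int,
    rng: np.random.Generator,
    score_scope: str = "causal",
    per_group: bool = False,
) -> dict:
    """Per-draw squared score-phenotype correlations for one configuration.

    Each draw redraws ancestral effects, regenerates the phenotype under
    ``model``, and scores every individual with both polygenic scores.
    Returns ``{'tot': {...}, 'par': {...}}`` where the inner dicts map
    ``'overall'`` (and subgroup ids when ``per_group``) to (n_draws,)
    arrays of squared correlations.
    """
    be, ba = ef.draw_ancestral_effects_batch(cov, cohort.la.p, n_draws, rng)
    sums = cohort.causal_sums
    if model == "local":
        g = sums["eur"] @ be + sums["afr"] @ ba
    elif model == "global":
        abar = cohort.abar[:, None]
        g = (1.0 - abar) * (sums["total"] @ be) + abar * (sums["total"] @ ba)
    else:
        raise ValueError("model must be 'local' or 'global'")
    var_g = g.var(axis=0)
    noise_sd = np.sqrt(np.clip(1.0 - var_g, 0.0, None))
    y = g + rng.standard_normal(g.shape) * noise_sd

    if score_scope == "causal":
        weights = be
        ssum = sums
    elif score_scope == "tagging":
        if cohort.tagging_sums is None:
            raise ValueError("cohort was built without tagging variants")
        weights = be * cohort.theta_eur_hat[:, None]
        ssum = cohort.tagging_sums
    else:
        raise ValueError("score_scope must be 'causal' or 'tagging'")
    tot = ssum["total"] @ weights
    par = ssum["eur"] @ weights

    out = {"tot": {"overall": _column_r2(tot, y)},
           "par": {"overall": _column_r2(par, y)}}
    if per_group:
        for gid in range(cohort.groups.n_groups):
            mask = cohort.groups.labels == gid
            out["tot"][gid] = _column_r2(tot[mask], y[mask])
            out["par"][gid] = _column_r2(par[mask], y[mask])
    return out


def _summarise(draws: dict, meta: dict) -> list[dict]:
    rows = []
    for score_type, by_group in draws.items():
        for subgroup, r2s in by_group.items():
            mean = float(np.mean(r2s))
            se = float(np.std(r2s, ddof=1) / np.sqrt(r2s.size))
            rows.append(
                dict(
                    meta,
                    score_type=score_type,
                    subgroup=subgroup,
                    mean_r2=mean,
                    se=se,
                    ci_lo=mean - 1.96 * se,
                    ci_hi=mean + 1.96 * se,
                    n_draws=int(r2s.size),
                )
            )
    return rows


def _run_study(cfg: ExperimentConfig, score_scope: str) -> pd.DataFrame:
    ss = np.random.SeedSequence(cfg.master_seed)
    rows = []
    for seed_idx, child in enumerate(ss.spawn(cfg.n_seeds)):
        rng = np.random.default_rng(child)
        cohort = build_cohort(cfg, rng)
        subgroup_abar = {
            gid: float(cohort.groups.group_means[gid])
            for gid in range(cohort.groups.n_groups)
        }
        for r2 in cfg.r2_grid:
            for rho in cfg.rho_grid:
                cov = ef.base_covariance(
                    cohort.causal_freqs, ef.EffectParams(r2=r2, rho=rho)
                )
                for model in ("global", "local"):
                    draws = simulate_r2_draws(
                        cohort, cov, model, cfg.n_draws, rng,
                        score_scope=score_scope, per_group=True,
                    )
                    meta = dict(
                        scenario=cfg.scenario, seed=seed_idx, model=model,
                        rho=rho, r2=r2,
                    )
                    rows.extend(_summarise(draws, meta))
        # stash subgroup means for theory comparisons
        for gid, m in subgroup_abar.items():
            rows.append(
                dict(
                    scenario=cfg.scenario, seed=seed_idx, model="(cohort)",
                    rho=np.nan, r2=np.nan, score_type="abar", subgroup=gid,
                    mean_r2=m, se=0.0, ci_lo=m, ci_hi=m, n_draws=0,
                )
            )
    return pd.DataFrame(rows)


def run_sim_study1(cfg: ExperimentConfig) -> pd.DataFrame:
    """Causal-variants-known study: PGSs built from European causal effects."""
    if cfg.scenario != "causal_known":
        raise ValueError("study 1 requires scenario='causal_known'")
    return _run_study(cfg, score_scope="causal")


def run_sim_study2(cfg: ExperimentConfig) -> pd.DataFrame:
    """Tagging-variant study: PGSs built from EUR-panel plug-in effects."""
    if cfg.scenario != "tagging":
        raise ValueError("study 2 requires scenario='tagging'")
    return _run_study(cfg, score_scope="tagging")


def distinguishability_grid(cfg: ExperimentConfig) -> pd.DataFrame:
    """Wilcoxon rank-sum model-distinguishability proportions per (rho, r2).

    For each cohort replicate and parameter pair, the per-draw squared
    correlations under the local and global models (independent draws) are
    compared with a two-sided Wilcoxon rank-sum test for each score type;
    the proportion of replicates significant at ``cfg.alpha`` is reported.
    """
    if cfg.n_draws < 20:
        raise ValueError("need at least 20 draws per model per bin")
    scope = "causal" if cfg.scenario == "causal_known" else "tagging"
    ss = np.random.SeedSequence(cfg.master_seed)
    hits = {}
    skipped = 0
    for child in ss.spawn(cfg.n_seeds):
        rng = np.random.default_rng(child)
        cohort = build_cohort(cfg, rng)
        for r2 in cfg.r2_grid:
            for rho in cfg.rho_grid:
                cov = ef.base_covariance(
                    cohort.causal_freqs, ef.EffectParams(r2=r2, rho=rho)
                )
                d_loc = simulate_r2_draws(cohort, cov, "local", cfg.n_draws, rng, scope)
                d_glo = simulate_r2_draws(cohort, cov, "global", cfg.n_draws, rng, scope)
                for score_type in ("tot", "par"):
                    a = d_loc[score_type]["overall"]
                    b = d_glo[score_type]["overall"]
                    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                        skipped += 1
                        continue
                    pval = stats.ranksums(a, b).pvalue
                    key = (rho, r2, score_type)
                    hits.setdefault(key, []).append(pval < cfg.alpha)
    rows = [
        dict(rho=rho, r2=r2, score_type=st,
             prop_significant=float(np.mean(v)), n_comparisons=len(v))
        for (rho, r2, st), v in hits.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["skipped_all_tied"] = skipped
    return df


def null_rejection_rate(
    cfg: ExperimentConfig,
    n_comparisons: int = 500,
    model: str = "global",
    rho: float = 0.5,
    r2: float = 0.4,
) -> float:
    """Rejection proportion when both Wilcoxon arms share the same model.

    Calibration check of the distinguishability test: each comparison draws
    two independent sets of ``cfg.n_draws`` per-draw squared correlations
    under the identical (model, rho, r2) configuration; the two-sided
    rank-sum test should reject at close to the nominal level.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed))
    cohort = build_cohort(cfg, rng, tagging=False)
    cov = ef.base_covariance(cohort.causal_freqs, ef.EffectParams(r2=r2, rho=rho))
    rejections = 0
    for _ in range(n_comparisons):
        a = simulate_r2_draws(cohort, cov, model, cfg.n_draws, rng)["par"]["overall"]
        b = simulate_r2_draws(cohort, cov, model, cfg.n_draws, rng)["par"]["overall"]
        if stats.ranksums(a, b).pvalue < cfg.alpha:
            rejections += 1
    return rejections / n_comparisons


def pooled_laacor_simulation(
    model: str,
    rho: float,
    n: int = 5000,
    p: int = 2000,
    n_redraws: int = 20,
    r2: float = 0.4,
    seed: int | np.random.SeedSequence = 0,
    beta_shape: tuple = cs.DEFAULT_BETA_SHAPE,
) -> float:
    """Genome-wide empirical LAACor on a calibrated synthetic cohort.

    Builds a cohort with Beta-distributed global ancestry and independent
    local-ancestry markers, redraws ancestral effects ``n_redraws`` times,
    computes per-variant conditional average effects by local ancestry
    under ``model``, and returns the mean (over redraws) of the sample
    correlation of the two average-effect vectors across variants.
    """
    from .ancestry_stats import (
        average_effects_batch,
        empirical_genome_wide_laacor,
        omega_weights,
    )

    rng = np.random.default_rng(seed)
    g = cs.sample_global_ancestry(n, beta_shape, seed=rng)
    la = cs.sample_local_ancestry(g, p, mode="independent", seed=rng)
    freqs = cs.sample_ancestral_frequencies(p, seed=rng)
    cov = ef.base_covariance(freqs, ef.EffectParams(r2=r2, rho=rho))
    om = omega_weights(la, g) if model == "global" else None
    be, ba = ef.draw_ancestral_effects_batch(cov, p, n_redraws, rng)
    avg_afr, avg_eur = average_effects_batch(model, be, ba, om)
    cors = np.asarray(empirical_genome_wide_laacor(avg_afr, avg_eur))
    return float(cors.mean())


def compare_to_theory(results: pd.DataFrame) -> pd.DataFrame:
    """Residuals of simulated mean squared correlations against closed forms.

    Uses each subgroup's realized mean African global ancestry (recorded in
    the results table) as the abar entering the closed forms; returns rows
    with the prediction, residual (simulated - predicted) and z-score
    against the Monte-Carlo standard error.
    """
    abar_rows = results[results["score_type"] == "abar"]
    if abar_rows.empty:
        raise ValueError("results table lacks recorded subgroup ancestry means")
    abar_map = {
        (row.seed, row.subgroup): row.mean_r2 for row in abar_rows.itertuples()
    }
    out = []
    sim = results[results["score_type"].isin(["tot", "par"])]
    for row in sim.itertuples():
        if row.subgroup == "overall":
            abar = np.mean(
                [v for (s, g), v in abar_map.items() if s == row.seed]
            )
        else:
            abar = abar_map[(row.seed, row.subgroup)]
        pred = predict(TheoryInputs(r2=row.r2, rho=row.rho, abar=float(abar)))
        if row.score_type == "tot":
            expected = pred.e_r2_tot
        else:
            expected = (
                pred.e_r2_par_global if row.model == "global" else pred.e_r2_par_local
            )
        resid = row.mean_r2 - expected
        out.append(
            dict(
                scenario=row.scenario, seed=row.seed, model=row.model,
                rho=row.rho, r2=row.r2, score_type=row.score_type,
                subgroup=row.subgroup, abar=float(abar), simulated=row.mean_r2,
                predicted=expected, residual=resid,
                z=resid / row.se if row.se > 0 else np.nan,
            )
        )
    return pd.DataFrame(out)
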