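"""Local-ancestry-conditioned statistics and average-effect correlations.

Implements ancestry-conditioned allele frequencies, the ancestry-specific
haplotypic LD estimator, conditional average effects by local ancestry, and
the closed-form joint distribution of those averages under the global model
(omega carrier weights and the (u, v, w) covariance terms), from which per
variant and genome-wide local-ancestry average-effect correlations (LAACor)
are computed.

Under the local model the average effect conditioned on a local ancestry is
exactly the ancestral effect of that ancestry, so the per-variant LAACor is
the base cross-ancestry correlation rho. Under the global model each
average is a carrier-weighted mix of both ancestral effects, which pushes
the correlation toward 1 whenever the spread of global ancestry among
carriers is small relative to its mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import (
    AncestryFrequencies,
    GlobalAncestryVector,
    HaplotypePanel,
    LocalAncestryPanel,
)
from .effects import BaseCovariance, IndividualEffectField

__all__ = [
    "ConditionalAverageEffects",
    "OmegaWeights",
    "LAACorReport",
    "conditional_allele_frequencies",
    "estimate_ld",
    "conditional_average_effects",
    "average_effects_batch",
    "omega_weights",
    "average_effect_covariance",
    "genome_wide_laacor",
    "empirical_genome_wide_laacor",
]


@dataclass(frozen=True)
class ConditionalAverageEffects:
    """Per-variant average effects by local ancestry, with carrier counts."""

    avg_afr: np.ndarray
    avg_eur: np.ndarray
    carriers_afr: np.ndarray
    carriers_eur: np.ndarray


@dataclass(frozen=True)
class OmegaWeights:
    """Carrier averages of (1 - abar, abar) by local ancestry per variant.

    w1/w2 average (1-abar_i, abar_i) over African-call carrier haplotypes;
    w3/w4 do the same over European-call carriers. w1 + w2 = 1 and
    w3 + w4 = 1 by construction; variants without carriers of an ancestry
    get NaN weights.
    """

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    w4: np.ndarray


@dataclass(frozen=True)
class LAACorReport:
    """Closed-form covariance terms and LAACor values (global model)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    laacor_per_variant: np.ndarray
    laacor_genomewide_closed: float
    scope: str = "causal"


def conditional_allele_frequencies(
    x: HaplotypePanel, la: LocalAncestryPanel
) -> AncestryFrequencies:
    """Sample allele frequency among haplotypes of each ancestry per variant.

    Variants with zero carrier haplotypes of an ancestry get NaN for that
    ancestry; downstream consumers must skip or reject them.
    """
    if x.alleles.shape != la.calls.shape:
        raise ValueError("haplotype and local-ancestry panels differ in shape")
    afr = la.calls == 1
    n_afr = afr.sum(axis=(0, 2)).astype(float)
    n_eur = (~afr).sum(axis=(0, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_afr = np.sum(x.alleles * afr, axis=(0, 2)) / np.where(n_afr > 0, n_afr, np.nan)
        f_eur = np.sum(x.alleles * ~afr, axis=(0, 2)) / np.where(n_eur > 0, n_eur, np.nan)
    return AncestryFrequencies(f_afr=f_afr, f_eur=f_eur, role=x.role)


def estimate_ld(
    xc: HaplotypePanel,
    xt: HaplotypePanel,
    la: LocalAncestryPanel,
    ancestry: str,
) -> np.ndarray:
    """Ancestry-specific haplotypic LD between paired causal/tagging variants.

    lambda = [P(X=1, X'=1) - f f'] / sqrt(f(1-f) f'(1-f')), computed on
    haplotypes whose local-ancestry call matches ``ancestry`` at the pair
    (pairs are positionally aligned and share local ancestry). Monomorphic
    variants within the stratum yield an error.
    """
    if ancestry not in ("afr", "eur"):
        raise ValueError("ancestry must be 'afr' or 'eur'")
    if xc.alleles.shape != xt.alleles.shape or xc.alleles.shape != la.calls.shape:
        raise ValueError("panels differ in shape")
    mask = la.calls == (1 if ancestry == "afr" else 0)
    n_str = mask.sum(axis=(0, 2)).astype(float)
    if (n_str < 2).any():
        raise ValueError("fewer than 2 haplotypes in the requested ancestry stratum")
    f_c = np.sum(xc.alleles * mask, axis=(0, 2)) / n_str
    f_t = np.sum(xt.alleles * mask, axis=(0, 2)) / n_str
    p11 = np.sum((xc.alleles & xt.alleles) * mask, axis=(0, 2)) / n_str
    denom2 = f_c * (1 - f_c) * f_t * (1 - f_t)
    if (denom2 <= 0).any():
        bad = np.flatnonzero(denom2 <= 0)
        raise ValueError(
            f"LD undefined: monomorphic variant(s) within '{ancestry}' stratum "
            f"at pairs {bad[:10].tolist()}"
        )
    return (p11 - f_c * f_t) / np.sqrt(denom2)


def conditional_average_effects(
    field: IndividualEffectField, la: LocalAncestryPanel | None = None
) -> ConditionalAverageEffects:
    """Average the individual effect over carrier haplotypes of each ancestry.

    A haplotype with an African call at variant j contributes its effect to
    the African average (diploid double-carriers contribute twice).
    Variants lacking carriers of an ancestry get NaN averages.
    """
    la = la if la is not None else field.la
    vals = field.materialize()
    afr = la.calls == 1
    n_afr = afr.sum(axis=(0, 2)).astype(float)
    n_eur = (~afr).sum(axis=(0, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_afr = np.einsum("ijh,ijh->j", vals, afr.astype(float)) / np.where(
            n_afr > 0, n_afr, np.nan
        )
        avg_eur = np.einsum("ijh,ijh->j", vals, (~afr).astype(float)) / np.where(
            n_eur > 0, n_eur, np.nan
        )
    return ConditionalAverageEffects(
        avg_afr=avg_afr,
        avg_eur=avg_eur,
        carriers_afr=n_afr.astype(int),
        carriers_eur=n_eur.astype(int),
    )


def average_effects_batch(
    model: str,
    beta_eur: np.ndarray,
    beta_afr: np.ndarray,
    omega: Optional[OmegaWeights] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional average effects for a batch of effect redraws.

    ``beta_eur``/``beta_afr`` are (p,) or (p, B). Local model: the averages
    are the ancestral effects themselves. Global model: the averages follow
    the carrier-weight identity avg_afr = w1 beta_Eur + w2 beta_Afr and
    avg_eur = w3 beta_Eur + w4 beta_Afr (exactly equal to the brute-force
    carrier average).
    """
    be = np.asarray(beta_eur, float)
    ba = np.asarray(beta_afr, float)
    if model == "local":
        return ba, be
    if model != "global":
        raise ValueError("model must be 'local' or 'global'")
    if omega is None:
        raise ValueError("global model requires omega weights")
    expand = (lambda w: w[:, None]) if be.ndim == 2 else (lambda w: w)
    avg_afr = expand(omega.w1) * be + expand(omega.w2) * ba
    avg_eur = expand(omega.w3) * be + expand(omega.w4) * ba
    return avg_afr, avg_eur


def omega_weights(
    la: LocalAncestryPanel, global_ancestry: GlobalAncestryVector | None = None
) -> OmegaWeights:
    """Carrier-haplotype averages of (1 - abar_i, abar_i) per variant."""
    if global_ancestry is None:
        global_ancestry = la.global_ancestry
    if global_ancestry is None:
        raise ValueError("global ancestry required for omega weights")
    abar = global_ancestry.values
    afr = la.calls == 1
    n_afr = afr.sum(axis=(0, 2)).astype(float)
    n_eur = (~afr).sum(axis=(0, 2)).astype(float)
    # sum of abar_i over carrier haplotypes (a double carrier counts twice)
    abar_sum_afr = np.einsum("i,ijh->j", abar, afr.astype(float))
    abar_sum_eur = np.einsum("i,ijh->j", abar, (~afr).astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        w2 = abar_sum_afr / np.where(n_afr > 0, n_afr, np.nan)
        w4 = abar_sum_eur / np.where(n_eur > 0, n_eur, np.nan)
    return OmegaWeights(w1=1.0 - w2, w2=w2, w3=1.0 - w4, w4=w4)


def average_effect_covariance(
    omega: OmegaWeights, cov: BaseCovariance, scope: str = "causal"
) -> LAACorReport:
    """Closed-form covariance of the two conditional average effects.

    u = Var(avg_afr), v = Var(avg_eur), w = Cov(avg_afr, avg_eur) under the
    global model, obtained by propagating the base bivariate-normal effect
    covariance through the carrier-weight identity:

        u = s2e w1^2 + 2 tau w1 w2 + s2a w2^2
        v = s2e w3^2 + 2 tau w3 w4 + s2a w4^2
        w = s2e w1 w3 + tau (w2 w3 + w1 w4) + s2a w2 w4
    """
    s2e, s2a, tau = cov.sigma2_eur, cov.sigma2_afr, cov.tau
    w1, w2, w3, w4 = omega.w1, omega.w2, omega.w3, omega.w4
    u = s2e * w1**2 + 2 * tau * w1 * w2 + s2a * w2**2
    v = s2e * w3**2 + 2 * tau * w3 * w4 + s2a * w4**2
    w = s2e * w1 * w3 + tau * (w2 * w3 + w1 * w4) + s2a * w2 * w4
    ok = ~(np.isnan(u) | np.isnan(v))
    if (u[ok] <= 0).any() or (v[ok] <= 0).any():
        raise ValueError("degenerate variance in conditional average effects")
    with np.errstate(invalid="ignore"):
        laacor = w / np.sqrt(u * v)
    pooled = genome_wide_laacor_from_terms(u, v, w)
    return LAACorReport(
        u=u, v=v, w=w, laacor_per_variant=laacor,
        laacor_genomewide_closed=pooled, scope=scope,
    )


def genome_wide_laacor_from_terms(
    u: np.ndarray, v: np.ndarray, w: np.ndarray
) -> float:
    """Pooled correlation sum(w) / sqrt(sum(u) sum(v)) over defined variants."""
    ok = ~(np.isnan(u) | np.isnan(v) | np.isnan(w))
    if ok.sum() < 2:
        raise ValueError("need at least 2 variants with defined covariance terms")
    return float(np.sum(w[ok]) / np.sqrt(np.sum(u[ok]) * np.sum(v[ok])))


def genome_wide_laacor(report: LAACorReport) -> float:
    """Pooled genome-wide LAACor parameter from a per-variant report."""
    return genome_wide_laacor_from_terms(report.u, report.v, report.w)


def empirical_genome_wide_laacor(
    avg_afr: np.ndarray, avg_eur: np.ndarray
) -> float | np.ndarray:
    """Sample correlation across variants of the realized average effects.

    Accepts (p,) vectors or (p, B) batches (one correlation per column).
    """
    a = np.asarray(avg_afr, float)
    e = np.asarray(avg_eur, float)
    ok = ~(np.isnan(a) | np.isnan(e))
    if a.ndim == 1:
        if ok.sum() < 2:
            raise ValueError("need at least 2 variants with defined averages")
        return float(np.corrcoef(a[ok], e[ok])[0, 1])
    a = np.where(ok, a, np.nan)
    ac = a - np.nanmean(a, axis=0)
    ec = e - np.nanmean(e, axis=0)
    ac = np.nan_to_num(ac)
    ec = np.nan_to_num(ec)
    num = np.sum(ac * ec, axis=0)
    den = np.sqrt(np.sum(ac**2, axis=0) * np.sum(ec**2, axis=0))
    return num / den
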