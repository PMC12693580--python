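"""Haplotype demeaning, phenotype simulation, and polygenic scores.

Demeaning subtracts the local-ancestry-matched allele frequency from each
haplotype dosage, making cumulative genetic effects invariant to allele
labelling. Phenotypes are the sum of individual-level effects times
demeaned dosages over both haplotypes plus normal noise calibrated so the
sample phenotypic variance is approximately 1. Two scores are computed from
European-ancestry effect sizes: the total polygenic score (TotPGS), which
weights every haplotype, and the partial polygenic score (ParPGS), which
weights only haplotypes of European local ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import (
    AncestryFrequencies,
    HaplotypePanel,
    LocalAncestryPanel,
    SubgroupAssignment,
)
from .effects import IndividualEffectField

__all__ = [
    "DemeanedHaplotypes",
    "PhenotypeSet",
    "PGSReport",
    "demean_haplotypes",
    "simulate_phenotype",
    "total_pgs",
    "partial_pgs",
    "pgs_phenotype_r2",
]


@dataclass(frozen=True)
class DemeanedHaplotypes:
    """Centered dosages x - f(local ancestry), shape (n, p, 2)."""

    values: np.ndarray
    frequencies_used: AncestryFrequencies

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def haplotype_sums(self, la: LocalAncestryPanel) -> dict:
        """Precomputed (n, p) sums for fast genetic-value matmuls."""
        eur_mask = la.calls == 0
        s_eur = np.sum(self.values * eur_mask, axis=2)
        s_tot = self.values.sum(axis=2)
        return {"total": s_tot, "eur": s_eur, "afr": s_tot - s_eur}


@dataclass(frozen=True)
class PhenotypeSet:
    """Simulated trait values with their realized variance decomposition."""

    y: np.ndarray
    model: str
    genetic_component: np.ndarray
    noise_variance: float


@dataclass(frozen=True)
class PGSReport:
    tot: np.ndarray
    par: np.ndarray
    r2_tot: dict
    r2_par: dict


def demean_haplotypes(
    x: HaplotypePanel,
    la: LocalAncestryPanel,
    freqs: AncestryFrequencies | None = None,
    freq_source: str = "true_generating",
) -> DemeanedHaplotypes:
    """Subtract the local-ancestry-matched allele frequency from each dosage.

    ``freq_source='true_generating'`` uses the supplied generating
    frequencies; ``'sample_conditional'`` re-estimates frequencies as
    ancestry-conditioned sample means first, which makes the demeaned
    dosages exactly mean-zero within each ancestry stratum at each variant.
    """
    if x.alleles.shape != la.calls.shape:
        raise ValueError("haplotype and local-ancestry panels differ in shape")
    if freq_source == "sample_conditional":
        from .ancestry_stats import conditional_allele_frequencies

        freqs = conditional_allele_frequencies(x, la)
    elif freq_source != "true_generating":
        raise ValueError("freq_source must be 'true_generating' or 'sample_conditional'")
    if freqs is None:
        raise ValueError("generating frequencies required for true_generating mode")
    if freqs.p != x.p:
        raise ValueError("frequency vector length does not match panel")
    fa, fe = freqs.f_afr, freqs.f_eur
    if np.isnan(fa).any() or np.isnan(fe).any():
        missing = np.flatnonzero(np.isnan(fa) | np.isnan(fe))
        raise ValueError(
            f"missing ancestry-conditioned frequency at variants {missing[:10].tolist()}"
        )
    f = np.where(la.calls == 1, fa[None, :, None], fe[None, :, None])
    return DemeanedHaplotypes(values=x.alleles - f, frequencies_used=freqs)


def simulate_phenotype(
    field: IndividualEffectField,
    xhat: DemeanedHaplotypes,
    la: LocalAncestryPanel,
    seed: int | np.random.Generator = 0,
) -> PhenotypeSet:
    """Simulate y = genetic value + normal noise with ~unit sample variance.

    The noise variance is calibrated per draw to max(0, 1 - Var(g)) where
    Var(g) is the realized sample variance of the genetic component.
    """
    rng = np.random.default_rng(seed)
    sums = xhat.haplotype_sums(la)
    g = field.genetic_component(sums)
    var_g = float(np.var(g))
    noise_var = 1.0 - var_g
    if noise_var < 0:
        warnings.warn(
            f"genetic variance {var_g:.3f} exceeds 1; noise variance floored at 0"
        )
        noise_var = 0.0
    y = g + rng.normal(scale=np.sqrt(noise_var), size=g.shape)
    return PhenotypeSet(
        y=y, model=field.model, genetic_component=g, noise_variance=noise_var
    )


def total_pgs(
    x: HaplotypePanel,
    la: LocalAncestryPanel,
    beta_eur_tag: np.ndarray,
    freqs: AncestryFrequencies | None = None,
    freq_source: str = "true_generating",
) -> np.ndarray:
    """TotPGS: European effects applied to every demeaned haplotype dosage."""
    xhat = demean_haplotypes(x, la, freqs, freq_source)
    return xhat.values.sum(axis=2) @ np.asarray(beta_eur_tag, float)


def partial_pgs(
    x: HaplotypePanel,
    la: LocalAncestryPanel,
    beta_eur_tag: np.ndarray,
    freqs: AncestryFrequencies | None = None,
    freq_source: str = "true_generating",
) -> np.ndarray:
    """ParPGS: European effects applied only on European-ancestry haplotypes."""
    xhat = demean_haplotypes(x, la, freqs, freq_source)
    masked = np.sum(xhat.values * (la.calls == 0), axis=2)
    return masked @ np.asarray(beta_eur_tag, float)


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero-variance input")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def pgs_phenotype_r2(
    scores: np.ndarray,
    pheno: PhenotypeSet | np.ndarray,
    groups: SubgroupAssignment | None = None,
) -> dict:
    """Squared Pearson correlation of score and phenotype, overall and per group.

    Returns a dict with key ``'overall'`` and, when a subgroup assignment is
    given, integer keys per subgroup.
    """
    y = pheno.y if isinstance(pheno, PhenotypeSet) else np.asarray(pheno, float)
    scores = np.asarray(scores, float)
    out = {"overall": _squared_pearson(scores, y)}
    if groups is not None:
        for g in range(groups.n_groups):
            mask = groups.labels == g
            if mask.sum() < 3:
                raise ValueError(f"subgroup {g} has fewer than 3 individuals")
            out[g] = _squared_pearson(scores[mask], y[mask])
    return out
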