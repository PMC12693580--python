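"""Ancestry-specific causal effects, tagging effects, and individual effects.

The base model draws per-variant European/African causal effects
(beta'_Eur, beta'_Afr) from a mean-zero bivariate normal whose variances are
set so that genetic effects explain a fraction r2 of phenotypic variance in
a homogeneous cohort, and whose correlation rho measures cross-ancestry
causal-effect similarity. Tagging effects are deterministic rescalings of
causal effects by ancestry-specific LD and allele-frequency ratios.
Individual-level effects expand ancestral effects under one of two
gene-by-ancestry interaction models:

* local model  — the effect on a haplotype is the ancestral effect of that
  haplotype's local ancestry at the variant (cis interaction);
* global model — the effect is the global-ancestry-weighted convex
  combination of the two ancestral effects, identical on both haplotypes
  (non-specific trans epistasis / ancestry-correlated G×E).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import AncestryFrequencies, LinkedPairMap, LocalAncestryPanel

__all__ = [
    "EffectParams",
    "BaseCovariance",
    "AncestralEffects",
    "ThetaScaling",
    "IndividualEffectField",
    "base_covariance",
    "draw_ancestral_effects",
    "theta_scaling",
    "tagging_effects",
    "individual_effects",
]


@dataclass(frozen=True)
class EffectParams:
    """Variance-explained r2 and cross-ancestry effect correlation rho."""

    r2: float
    rho: float

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")
        if abs(self.rho) > 1.0:
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class BaseCovariance:
    """Covariance of the bivariate ancestral-effect distribution."""

    sigma2_eur: float
    sigma2_afr: float
    tau: float

    def __post_init__(self):
        if self.sigma2_eur <= 0 or self.sigma2_afr <= 0:
            raise ValueError("effect variances must be positive")
        if abs(self.tau) > np.sqrt(self.sigma2_eur * self.sigma2_afr) + 1e-12:
            raise ValueError("|tau| exceeds sqrt(sigma2_eur * sigma2_afr)")

    @property
    def rho(self) -> float:
        return self.tau / np.sqrt(self.sigma2_eur * self.sigma2_afr)

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_eur, self.tau], [self.tau, self.sigma2_afr]]
        )


@dataclass(frozen=True)
class ThetaScaling:
    """Per-pair causal-to-tagging effect scaling factors."""

    theta_eur: np.ndarray
    theta_afr: np.ndarray


@dataclass(frozen=True)
class AncestralEffects:
    """Per-variant causal effects with optional derived tagging effects."""

    beta_eur: np.ndarray
    beta_afr: np.ndarray
    params: Optional[EffectParams] = None
    tag_beta_eur: Optional[np.ndarray] = None
    tag_beta_afr: Optional[np.ndarray] = None
    theta: Optional[ThetaScaling] = None

    @property
    def p(self) -> int:
        return np.asarray(self.beta_eur).shape[0]


def base_covariance(
    freqs: AncestryFrequencies, params: EffectParams
) -> BaseCovariance:
    """Build the ancestral-effect covariance from causal allele frequencies.

    sigma2_Eur = r2 / (2 sum_j f'_Eur,j (1 - f'_Eur,j)), analogously for the
    African background, and tau = r2 rho / (2 sqrt(S_Eur S_Afr)) where S is
    the per-ancestry heterozygosity sum. This normalisation makes the
    genetic variance of a homogeneous cohort approximately r2.
    """
    fe, fa = freqs.f_eur, freqs.f_afr
    if np.any((fe <= 0) | (fe >= 1)) or np.any((fa <= 0) | (fa >= 1)):
        raise ValueError("causal frequencies must lie strictly in (0, 1)")
    s_eur = float(np.sum(fe * (1.0 - fe)))
    s_afr = float(np.sum(fa * (1.0 - fa)))
    sigma2_eur = params.r2 / (2.0 * s_eur)
    sigma2_afr = params.r2 / (2.0 * s_afr)
    tau = params.r2 * params.rho / (2.0 * np.sqrt(s_eur * s_afr))
    return BaseCovariance(sigma2_eur=sigma2_eur, sigma2_afr=sigma2_afr, tau=tau)


def draw_ancestral_effects(
    cov: BaseCovariance,
    p: int,
    seed: int | np.random.Generator = 0,
    params: Optional[EffectParams] = None,
) -> AncestralEffects:
    """Draw (beta'_Eur, beta'_Afr) i.i.d. bivariate normal across variants."""
    rng = np.random.default_rng(seed)
    be, ba = draw_ancestral_effects_batch(cov, p, 1, rng)
    return AncestralEffects(beta_eur=be[:, 0], beta_afr=ba[:, 0], params=params)


def draw_ancestral_effects_batch(
    cov: BaseCovariance, p: int, n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised effect redraws: two (p, n_draws) arrays (Eur, Afr).

    Uses the direct construction beta_Afr = sigma_Afr (rho z1 +
    sqrt(1-rho^2) z2), which stays valid at |rho| = 1 where the covariance
    matrix is singular.
    """
    se = np.sqrt(cov.sigma2_eur)
    sa = np.sqrt(cov.sigma2_afr)
    rho = np.clip(cov.tau / (se * sa), -1.0, 1.0)
    if 1.0 - abs(rho) < 1e-9:  # keep |rho|=1 exactly proportional
        rho = np.sign(rho)
    z1 = rng.standard_normal((p, n_draws))
    z2 = rng.standard_normal((p, n_draws))
    return se * z1, sa * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)


def theta_scaling(
    pairs: LinkedPairMap,
    causal_freqs: AncestryFrequencies,
    tagging_freqs: AncestryFrequencies,
) -> ThetaScaling:
    """theta = lambda * sqrt(f'(1-f') / f(1-f)) per ancestry and pair."""
    for f in (causal_freqs, tagging_freqs):
        if np.any((f.f_eur <= 0) | (f.f_eur >= 1)) or np.any(
            (f.f_afr <= 0) | (f.f_afr >= 1)
        ):
            raise ValueError("frequencies must lie strictly in (0, 1)")
    ci = np.asarray(pairs.pairs)[:, 0]
    ti = np.asarray(pairs.pairs)[:, 1]

    def _theta(lam, fc, ft):
        return lam * np.sqrt(fc[ci] * (1 - fc[ci]) / (ft[ti] * (1 - ft[ti])))

    return ThetaScaling(
        theta_eur=_theta(np.asarray(pairs.lambda_eur), causal_freqs.f_eur, tagging_freqs.f_eur),
        theta_afr=_theta(np.asarray(pairs.lambda_afr), causal_freqs.f_afr, tagging_freqs.f_afr),
    )


def tagging_effects(
    effects: AncestralEffects,
    pairs: LinkedPairMap,
    causal_freqs: AncestryFrequencies,
    tagging_freqs: AncestryFrequencies,
) -> AncestralEffects:
    """Fill in tagging effects beta = beta' * theta for each ancestry.

    Tagging effects are taken as exactly the LD/frequency rescaling of the
    causal effects (no estimation noise): the induced tagging-effect
    distribution is the base bivariate normal with variances scaled by
    theta^2 and covariance by theta_Eur theta_Afr.
    """
    th = theta_scaling(pairs, causal_freqs, tagging_freqs)
    return AncestralEffects(
        beta_eur=effects.beta_eur,
        beta_afr=effects.beta_afr,
        params=effects.params,
        tag_beta_eur=effects.beta_eur * th.theta_eur,
        tag_beta_afr=effects.beta_afr * th.theta_afr,
        theta=th,
    )


class IndividualEffectField:
    """Per-(individual, variant, haplotype) effects under a named model.

    The field is represented lazily: ``materialize`` produces the full
    (n, p, 2) array (a broadcast view for the global model, whose effects
    are identical across haplotypes).
    """

    def __init__(
        self,
        model: str,
        beta_eur: np.ndarray,
        beta_afr: np.ndarray,
        la: LocalAncestryPanel,
    ):
        if model not in ("local", "global"):
            raise ValueError("model must be 'local' or 'global'")
        self.model = model
        self.beta_eur = np.asarray(beta_eur, float)
        self.beta_afr = np.asarray(beta_afr, float)
        self.la = la
        if self.beta_eur.shape != (la.p,) or self.beta_afr.shape != (la.p,):
            raise ValueError("effect vectors must have length p")
        if model == "global":
            if la.global_ancestry is None:
                raise ValueError("global model requires global ancestry")
            self.abar = la.global_ancestry.values
        else:
            self.abar = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.la.n, self.la.p, 2)

    def materialize(self) -> np.ndarray:
        delta = self.beta_afr - self.beta_eur
        if self.model == "local":
            return self.beta_eur[None, :, None] + delta[None, :, None] * self.la.calls
        vals = self.beta_eur[None, :] + np.outer(self.abar, delta)
        return np.broadcast_to(vals[:, :, None], self.shape)

    def genetic_component(self, xhat_sum_by_mask) -> np.ndarray:
        """Per-individual genetic value given precomputed demeaned sums.

        ``xhat_sum_by_mask`` is a dict with keys ``total``, ``eur``, ``afr``
        mapping to (n, p) sums of demeaned dosages over both haplotypes,
        over European-call haplotypes, and over African-call haplotypes.
        """
        if self.model == "local":
            return (
                xhat_sum_by_mask["eur"] @ self.beta_eur
                + xhat_sum_by_mask["afr"] @ self.beta_afr
            )
        s = xhat_sum_by_mask["total"]
        return (1.0 - self.abar) * (s @ self.beta_eur) + self.abar * (
            s @ self.beta_afr
        )


def individual_effects(
    model: str,
    effects: AncestralEffects,
    la: LocalAncestryPanel,
    scope: str = "causal",
) -> IndividualEffectField:
    """Expand ancestral effects into an individual-level effect field.

    ``scope='causal'`` uses the causal effects; ``scope='tagging'`` uses the
    derived tagging effects (which must have been filled in).
    """
    if scope == "causal":
        be, ba = effects.beta_eur, effects.beta_afr
    elif scope == "tagging":
        if effects.tag_beta_eur is None:
            raise ValueError("tagging effects not filled in")
        be, ba = effects.tag_beta_eur, effects.tag_beta_afr
    else:
        raise ValueError("scope must be 'causal' or 'tagging'")
    return IndividualEffectField(model, be, ba, la)
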