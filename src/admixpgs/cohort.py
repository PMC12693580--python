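"""Synthetic two-way admixed cohort generation.

Generates the building blocks of an African/European admixed cohort:
per-individual global ancestry proportions, binary local-ancestry mosaics
over phased haplotypes, ancestry-specific allele frequencies, phased binary
haplotypes conditional on local ancestry, and causal--tagging variant pairs
with specified ancestry-specific LD.

Conventions used throughout the package: ancestry is coded 1 = African,
0 = European; panels are ``(n, p, 2)`` arrays indexed by (individual,
variant, haplotype); global ancestry is the genome-wide mean of an
individual's local-ancestry calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GlobalAncestryVector",
    "LocalAncestryPanel",
    "AncestryFrequencies",
    "HaplotypePanel",
    "LinkedPairMap",
    "SubgroupAssignment",
    "DEFAULT_BETA_SHAPE",
    "sample_global_ancestry",
    "sample_local_ancestry",
    "sample_ancestral_frequencies",
    "sample_haplotypes",
    "sample_linked_pairs",
    "split_subgroups",
    "compute_global_ancestry",
]

#: Beta shape parameters for African global ancestry, calibrated so that the
#: quartile-subgroup means of the sampled distribution approximate
#: (0.61, 0.79, 0.85, 0.92), the subgroup structure this simulator emulates.
DEFAULT_BETA_SHAPE = (7.4812, 1.9424)


@dataclass(frozen=True)
class GlobalAncestryVector:
    """African global ancestry proportion per individual (``abar_i``)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("global ancestry must be a 1-d vector")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("global ancestry values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LocalAncestryPanel:
    """Binary local-ancestry calls, shape (n, p, 2); 1 = African."""

    calls: np.ndarray
    variant_positions: Optional[np.ndarray] = None  # Morgans
    global_ancestry: Optional[GlobalAncestryVector] = None

    def __post_init__(self):
        c = np.asarray(self.calls)
        if c.ndim != 3 or c.shape[2] != 2:
            raise ValueError("local-ancestry calls must have shape (n, p, 2)")
        if c.size and not np.isin(c, (0, 1)).all():
            raise ValueError("local-ancestry calls must be exactly 0 or 1")
        object.__setattr__(self, "calls", c.astype(np.int8))
        if self.variant_positions is not None:
            pos = np.asarray(self.variant_positions, dtype=float)
            if pos.shape != (c.shape[1],):
                raise ValueError("variant_positions length must equal p")
            object.__setattr__(self, "variant_positions", pos)

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def p(self) -> int:
        return self.calls.shape[1]


@dataclass(frozen=True)
class AncestryFrequencies:
    """Ancestry-specific allele frequencies per variant."""

    f_afr: np.ndarray
    f_eur: np.ndarray
    role: str = "causal"  # causal | tagging

    def __post_init__(self):
        fa = np.asarray(self.f_afr, dtype=float)
        fe = np.asarray(self.f_eur, dtype=float)
        if fa.shape != fe.shape or fa.ndim != 1:
            raise ValueError("frequency vectors must be 1-d and equal length")
        for f in (fa, fe):
            defined = f[~np.isnan(f)]
            if defined.size and (defined.min() < 0 or defined.max() > 1):
                raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "f_afr", fa)
        object.__setattr__(self, "f_eur", fe)

    @property
    def p(self) -> int:
        return self.f_afr.shape[0]


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased binary allele dosages, shape (n, p, 2)."""

    alleles: np.ndarray
    variant_ids: Optional[Sequence[str]] = None
    role: str = "causal"

    def __post_init__(self):
        a = np.asarray(self.alleles)
        if a.ndim != 3 or a.shape[2] != 2:
            raise ValueError("haplotype alleles must have shape (n, p, 2)")
        if a.size and not np.isin(a, (0, 1)).all():
            raise ValueError("alleles must be exactly 0 or 1")
        object.__setattr__(self, "alleles", a.astype(np.int8))
        if self.variant_ids is None:
            object.__setattr__(
                self, "variant_ids", [f"v{j}" for j in range(a.shape[1])]
            )

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def p(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class LinkedPairMap:
    """Causal--tagging pair assignment with ancestry-specific LD targets."""

    pairs: np.ndarray  # (p, 2) int, columns (causal index, tagging index)
    lambda_afr: np.ndarray
    lambda_eur: np.ndarray
    realized_lambda_afr: Optional[np.ndarray] = None
    realized_lambda_eur: Optional[np.ndarray] = None

    @property
    def p(self) -> int:
        return np.asarray(self.pairs).shape[0]


@dataclass(frozen=True)
class SubgroupAssignment:
    """Global-ancestry-ranked subgroup labels with per-group means."""

    labels: np.ndarray
    group_means: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.group_means.shape[0]


def sample_global_ancestry(
    n: int,
    shape_params: tuple[float, float] = DEFAULT_BETA_SHAPE,
    seed: int | np.random.Generator = 0,
) -> GlobalAncestryVector:
    """Draw i.i.d. Beta-distributed African global ancestry proportions.

    The default shape parameters are calibrated so that splitting a large
    cohort into global-ancestry quartiles yields subgroup means close to
    (0.61, 0.79, 0.85, 0.92) with overall mean ~0.79.
    """
    a, b = shape_params
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return GlobalAncestryVector(rng.beta(a, b, size=n))


def sample_local_ancestry(
    global_ancestry: GlobalAncestryVector,
    p: int,
    mode: str = "independent",
    map_length: float = 1.0,
    generations: int = 15,
    seed: int | np.random.Generator = 0,
) -> LocalAncestryPanel:
    """Simulate binary local-ancestry mosaics for each haplotype.

    ``independent`` mode draws each call i.i.d. Bernoulli(abar_i): the clean
    analogue of a panel of approximately independent markers. ``tract`` mode
    lays markers uniformly on a genetic map of ``map_length`` Morgans and
    runs a two-state Markov chain per haplotype: ancestry breakpoints occur
    at rate ``generations`` per Morgan and each breakpoint redraws the
    ancestral state Bernoulli(abar_i) — the standard single-pulse admixture
    approximation with admixture ``generations`` generations ago.
    """
    abar = global_ancestry.values
    if abar.size == 0:
        raise ValueError("global ancestry vector is empty")
    if p < 1:
        raise ValueError("p must be at least 1")
    rng = np.random.default_rng(seed)
    n = abar.shape[0]

    if mode == "independent":
        u = rng.random((n, p, 2))
        calls = (u < abar[:, None, None]).astype(np.int8)
        return LocalAncestryPanel(
            calls, variant_positions=None, global_ancestry=global_ancestry
        )

    if mode != "tract":
        raise ValueError(f"unknown mode {mode!r}")
    if map_length <= 0:
        raise ValueError("map_length must be positive in tract mode")
    if generations < 1:
        raise ValueError("generations must be >= 1 in tract mode")

    pos = np.linspace(0.0, map_length, p)
    gaps = np.diff(pos)
    # P(at least one breakpoint between adjacent markers); a breakpoint
    # redraws ancestry from the stationary Bernoulli(abar_i) distribution.
    p_break = 1.0 - np.exp(-generations * gaps)  # (p-1,)
    calls = np.empty((n, p, 2), dtype=np.int8)
    calls[:, 0, :] = rng.random((n, 2)) < abar[:, None]
    redraw = rng.random((n, p - 1, 2)) < p_break[None, :, None]
    new_state = rng.random((n, p - 1, 2)) < abar[:, None, None]
    for j in range(1, p):
        prev = calls[:, j - 1, :]
        calls[:, j, :] = np.where(redraw[:, j - 1, :], new_state[:, j - 1, :], prev)
    return LocalAncestryPanel(
        calls, variant_positions=pos, global_ancestry=global_ancestry
    )


def sample_ancestral_frequencies(
    p: int,
    fst: float = 0.15,
    base_dist=None,
    seed: int | np.random.Generator = 0,
    role: str = "causal",
) -> AncestryFrequencies:
    """Draw ancestry-specific allele frequencies via a Balding–Nichols model.

    An ancestral frequency q is drawn per variant (default Uniform(0.05,
    0.95)); African and European frequencies are then drawn independently
    from Beta(q(1-Fst)/Fst, (1-q)(1-Fst)/Fst) and clipped to [0.01, 0.99]
    to protect downstream 1/sqrt(f(1-f)) scalings.
    """
    if not (0 < fst < 1):
        raise ValueError("fst must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    if base_dist is None:
        q = rng.uniform(0.05, 0.95, size=p)
    else:
        q = np.asarray(base_dist(rng, p), dtype=float)
    scale = (1.0 - fst) / fst
    f_afr = rng.beta(q * scale, (1.0 - q) * scale)
    f_eur = rng.beta(q * scale, (1.0 - q) * scale)
    return AncestryFrequencies(
        f_afr=np.clip(f_afr, 0.01, 0.99),
        f_eur=np.clip(f_eur, 0.01, 0.99),
        role=role,
    )


def sample_haplotypes(
    la: LocalAncestryPanel,
    freqs: AncestryFrequencies,
    seed: int | np.random.Generator = 0,
    role: str | None = None,
) -> HaplotypePanel:
    """Draw alleles Bernoulli(f_afr) on African calls, Bernoulli(f_eur) else."""
    if freqs.p != la.p:
        raise ValueError(
            f"frequency vector length {freqs.p} does not match panel p={la.p}"
        )
    rng = np.random.default_rng(seed)
    f = np.where(la.calls == 1, freqs.f_afr[None, :, None], freqs.f_eur[None, :, None])
    alleles = (rng.random(la.calls.shape) < f).astype(np.int8)
    return HaplotypePanel(alleles, role=role or freqs.role)


def _joint_bernoulli_p11(f, f2, lam):
    """P(X=1, X'=1) implied by marginals and haplotypic correlation lam."""
    return f * f2 + lam * np.sqrt(f * (1 - f) * f2 * (1 - f2))


def sample_linked_pairs(
    causal_freqs: AncestryFrequencies,
    tagging_freqs: AncestryFrequencies,
    target_lambda_afr: np.ndarray | float,
    target_lambda_eur: np.ndarray | float,
    la: LocalAncestryPanel,
    seed: int | np.random.Generator = 0,
) -> tuple[HaplotypePanel, HaplotypePanel, LinkedPairMap]:
    """Jointly draw causal and tagging alleles with ancestry-specific LD.

    Each causal variant j is paired with tagging variant j. Within each
    ancestry background, the pair of alleles on a haplotype is drawn from
    the bivariate Bernoulli with marginals (f'_j, f_j) and haplotypic
    correlation lambda, so P(1,1) = f f' + lambda sqrt(f(1-f) f'(1-f')).
    Both members of a pair share the haplotype's local-ancestry call
    (causal and tagging variants are tightly linked).
    """
    p = causal_freqs.p
    if tagging_freqs.p != p or la.p != p:
        raise ValueError("causal/tagging frequencies and panel must share p")
    lam_a = np.broadcast_to(np.asarray(target_lambda_afr, float), (p,)).copy()
    lam_e = np.broadcast_to(np.asarray(target_lambda_eur, float), (p,)).copy()

    cond_p1 = {}  # ancestry -> (P(tag=1 | causal=1), P(tag=1 | causal=0))
    for anc, lam, fc, ft in (
        ("afr", lam_a, causal_freqs.f_afr, tagging_freqs.f_afr),
        ("eur", lam_e, causal_freqs.f_eur, tagging_freqs.f_eur),
    ):
        p11 = _joint_bernoulli_p11(fc, ft, lam)
        lo = np.maximum(0.0, fc + ft - 1.0)
        hi = np.minimum(fc, ft)
        bad = (p11 < lo - 1e-12) | (p11 > hi + 1e-12)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"infeasible LD target for pair {j} ({anc}): lambda={lam[j]:.4f} "
                f"with f'={fc[j]:.4f}, f={ft[j]:.4f} violates Frechet bounds"
            )
        p11 = np.clip(p11, lo, hi)
        cond_p1[anc] = (p11 / fc, (ft - p11) / (1.0 - fc))

    rng = np.random.default_rng(seed)
    causal = sample_haplotypes(la, causal_freqs, seed=rng, role="causal")
    xc = causal.alleles
    afr = la.calls == 1
    p1_given_c1 = np.where(afr, cond_p1["afr"][0][None, :, None], cond_p1["eur"][0][None, :, None])
    p1_given_c0 = np.where(afr, cond_p1["afr"][1][None, :, None], cond_p1["eur"][1][None, :, None])
    p_tag = np.where(xc == 1, p1_given_c1, p1_given_c0)
    xt = (rng.random(xc.shape) < p_tag).astype(np.int8)
    tagging = HaplotypePanel(xt, role="tagging")

    pairs = np.column_stack([np.arange(p), np.arange(p)])
    pair_map = LinkedPairMap(pairs=pairs, lambda_afr=lam_a, lambda_eur=lam_e)
    return causal, tagging, pair_map


def split_subgroups(
    global_ancestry: GlobalAncestryVector, n_groups: int = 4
) -> SubgroupAssignment:
    """Rank individuals by global ancestry and cut into equal-size groups."""
    n = global_ancestry.n
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n < n_groups:
        raise ValueError(f"cannot split {n} individuals into {n_groups} groups")
    order = np.argsort(global_ancestry.values, kind="stable")
    labels = np.empty(n, dtype=int)
    bounds = (n * np.arange(n_groups + 1)) // n_groups
    for g in range(n_groups):
        labels[order[bounds[g] : bounds[g + 1]]] = g
    means = np.array(
        [global_ancestry.values[labels == g].mean() for g in range(n_groups)]
    )
    return SubgroupAssignment(labels=labels, group_means=means)


def compute_global_ancestry(la: LocalAncestryPanel) -> GlobalAncestryVector:
    """Global ancestry as the genome-wide mean of local-ancestry calls."""
    if la.p < 1:
        raise ValueError("panel has no variants")
    return GlobalAncestryVector(la.calls.mean(axis=(1, 2)))
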