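"""Closed-form predictions for causal-variant polygenic score performance.

With causal variants and their European effects known, the expected squared
correlation between each polygenic score and the phenotype admits simple
closed forms in (r2, rho, abar), where abar is the cohort mean African
global ancestry. These approximations hold under simplifying conditions on
the cohort — uniform allele frequencies across markers, a shared
local-ancestry distribution across individuals, concordant ancestry between
an individual's two haplotypes, small between-ancestry frequency gaps, and
approximately independent haplotypes — but remain qualitatively accurate
well outside them.

* TotPGS (either model):   r2 (1 - abar + rho abar)^2
* ParPGS, global model:    r2 (1 - abar) (1 - abar + rho abar)^2
* ParPGS, local model:     r2 (1 - abar)

Under the local model the partial score beats the total score exactly when
1 - abar >= (rho / (1 - rho))^2, i.e. for rho below
sqrt(1-abar) / (1 + sqrt(1-abar)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryInputs",
    "TheoryPrediction",
    "expected_r2_totpgs",
    "expected_r2_parpgs_global",
    "expected_r2_parpgs_local",
    "parpgs_advantage_threshold",
    "relative_predictive_power",
    "predict",
    "conditions_diagnostic",
]


@dataclass(frozen=True)
class TheoryInputs:
    r2: float
    rho: float
    abar: float

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")
        if abs(self.rho) > 1.0:
            raise ValueError("|rho| must be <= 1")
        if not (0.0 <= self.abar <= 1.0):
            raise ValueError("abar must lie in [0, 1]")


@dataclass(frozen=True)
class TheoryPrediction:
    e_r2_tot: float
    e_r2_par_global: float
    e_r2_par_local: float
    conditions_note: str = (
        "valid under simplifying cohort conditions (uniform frequencies, "
        "shared ancestry distribution, haplotype concordance, small "
        "frequency gaps, independent haplotypes)"
    )


def expected_r2_totpgs(inp: TheoryInputs) -> float:
    """E[Cor^2(TotPGS, y)] ~ r2 (1 - abar + rho abar)^2, either model."""
    return inp.r2 * (1.0 - inp.abar + inp.rho * inp.abar) ** 2


def expected_r2_parpgs_global(inp: TheoryInputs) -> float:
    """E_Glo[Cor^2(ParPGS, y)] ~ r2 (1 - abar)(1 - abar + rho abar)^2."""
    return inp.r2 * (1.0 - inp.abar) * (1.0 - inp.abar + inp.rho * inp.abar) ** 2


def expected_r2_parpgs_local(inp: TheoryInputs) -> float:
    """E_Loc[Cor^2(ParPGS, y)] ~ r2 (1 - abar); independent of rho."""
    return inp.r2 * (1.0 - inp.abar)


def parpgs_advantage_threshold(abar: float) -> float:
    """Largest rho at which the local-model ParPGS outperforms TotPGS.

    Solves 1 - abar = (rho / (1 - rho))^2 for rho, giving
    rho* = sqrt(1 - abar) / (1 + sqrt(1 - abar)); at abar = 0.8 this is
    ~0.31, and it tends to 0.5 as abar -> 0.
    """
    if not (0.0 < abar < 1.0):
        raise ValueError("abar must lie strictly in (0, 1)")
    s = np.sqrt(1.0 - abar)
    return float(s / (1.0 + s))


def relative_predictive_power(model: str, inp: TheoryInputs) -> float:
    """Expected ratio E[Cor^2(ParPGS, y)] / E[Cor^2(TotPGS, y)].

    Global model: exactly the European global ancestry 1 - abar (the
    'prediction shrinkage factor'), independent of r2 and rho. Local model:
    (1 - abar) / (1 - abar + rho abar)^2, strictly decreasing in rho.
    """
    if model == "global":
        return 1.0 - inp.abar
    if model != "local":
        raise ValueError("model must be 'local' or 'global'")
    denom = (1.0 - inp.abar + inp.rho * inp.abar) ** 2
    if denom == 0:
        raise ValueError("degenerate: TotPGS expectation is zero")
    return (1.0 - inp.abar) / denom


def predict(inp: TheoryInputs) -> TheoryPrediction:
    """All three closed forms bundled for one (r2, rho, abar) point."""
    return TheoryPrediction(
        e_r2_tot=expected_r2_totpgs(inp),
        e_r2_par_global=expected_r2_parpgs_global(inp),
        e_r2_par_local=expected_r2_parpgs_local(inp),
    )


def conditions_diagnostic(la, freqs) -> dict:
    """Quantify how strongly a cohort violates the closed forms' conditions.

    Returns summary statistics, one per condition: the coefficient of
    variation of per-ancestry heterozygosity across markers (uniform
    frequencies), the standard deviation of global ancestry (shared
    ancestry distribution), the mean within-individual haplotype
    ancestry discordance (haplotype concordance), the maximum absolute
    between-ancestry frequency gap (small gaps), and the mean absolute
    between-haplotype allele-call correlation (haplotype independence is
    not directly observable from calls alone, so the ancestry-call
    correlation is reported). Nothing is enforced; the numbers let a user
    judge how far a cohort sits from the idealised regime.
    """
    het_e = freqs.f_eur * (1 - freqs.f_eur)
    het_a = freqs.f_afr * (1 - freqs.f_afr)
    abar = (
        la.global_ancestry.values
        if la.global_ancestry is not None
        else la.calls.mean(axis=(1, 2))
    )
    discord = float(np.mean(la.calls[:, :, 0] != la.calls[:, :, 1]))
    c1, c2 = la.calls[:, :, 0].astype(float), la.calls[:, :, 1].astype(float)
    c1 = c1 - c1.mean(axis=0)
    c2 = c2 - c2.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hap_cor = np.nansum(c1 * c2, axis=0) / np.sqrt(
            np.sum(c1**2, axis=0) * np.sum(c2**2, axis=0)
        )
    return {
        "freq_heterozygosity_cv": float(
            0.5 * (np.std(het_e) / np.mean(het_e) + np.std(het_a) / np.mean(het_a))
        ),
        "global_ancestry_sd": float(np.std(abar)),
        "haplotype_ancestry_discordance": discord,
        "max_frequency_gap": float(np.max(np.abs(freqs.f_afr - freqs.f_eur))),
        "mean_abs_interhaplotype_ancestry_cor": float(np.nanmean(np.abs(hap_cor))),
    }
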