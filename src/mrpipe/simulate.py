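"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly on the summary scale: true per-SNP exposure
associations are fixed, true outcome associations follow the linear causal
model Gamma_j = theta * gamma_j + alpha_j (alpha = direct pleiotropic
effect), and estimated statistics are drawn with the sampling variance a GWAS
of the given size would produce, optionally with LD-correlated noise across
SNPs.  The two samples are non-overlapping, so exposure and outcome noise are
independent.

Default scenario parameters mirror the study design the estimators target:
an exposure GWAS of 8631 adults explaining R^2 = 0.15 with 47 correlated
functional-gene variants, and a case-control outcome sample of 340,799
(76,014 cases) on the log-odds scale with a causal OR of 0.97 per unit
exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .estimators import WaldEstimate, _weighted_median
from .io import LDMatrix, SummaryAssociation

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

FUNCTIONAL_GENES = ("FADS1", "FADS2", "NTAN1")


@dataclass(frozen=True)
class SimulationScenario:
    """Configuration of one synthetic two-sample dataset."""

    n_snps: int = 47
    n_exposure_sample: int = 8631
    n_outcome_sample: int = 340799
    case_fraction: Optional[float] = 76014 / 340799
    target_r2: float = 0.15
    ld_rho: float = 0.5
    causal_effect: float = math.log(0.97)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 < 1):
            raise ValidationError(f"target_r2 {self.target_r2} outside (0, 1)")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValidationError("invalid_fraction outside [0, 1]")
        if abs(self.ld_rho) >= 1:
            raise ValidationError("|ld_rho| must be < 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction outside (0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """The generator's ground truth for one dataset."""

    theta: float
    per_snp_gamma: np.ndarray
    per_snp_alpha: np.ndarray
    seed: int


def make_ld_ar1(n_snps: int, rho: float) -> LDMatrix:
    """AR(1) correlation structure r[i,j] = rho^|i-j| — PSD by construction."""
    if abs(rho) >= 1:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)
    return LDMatrix([f"rs{i + 1}" for i in range(n_snps)], r)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, 5e-324, 1.0)


def _table(
    snp_ids: Sequence[str],
    alleles: Sequence[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait: str,
    genes: Optional[Sequence[Optional[str]]] = None,
) -> list[SummaryAssociation]:
    p = _two_sided_p(beta / se)
    return [
        SummaryAssociation(
            snp_id=snp_ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(p[j]),
            n=n,
            trait=trait,
            gene=None if genes is None else genes[j],
        )
        for j in range(len(snp_ids))
    ]


def simulate_two_sample(
    scenario: SimulationScenario,
) -> tuple[list[SummaryAssociation], list[SummaryAssociation], LDMatrix, SyntheticTruth]:
    """Draw one synthetic exposure table, outcome table, LD matrix and truth.

    Per-SNP exposure effects share the target R^2 equally: with MAF f_j drawn
    uniform(0.05, 0.5), gamma_j = s_j * sqrt((R^2/J) / (2 f_j (1-f_j))) with
    random sign s_j, so that sum 2f(1-f) gamma^2 = R^2 on a unit-variance
    exposure.  ceil(invalid_fraction * J) randomly chosen SNPs get direct
    effects alpha_j (balanced: mean 0; directional: mean pleiotropy_mean).
    Sampling noise has per-SNP scale set by sample size and allele frequency
    (binary outcomes on the log-odds scale with the case-fraction-adjusted
    variance 1/(N K(1-K) 2f(1-f))) and is correlated across SNPs through the
    Cholesky factor of the LD matrix.  Deterministic given the seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    J = sc.n_snps
    snp_ids = [f"rs{j + 1}" for j in range(J)]
    ld = make_ld_ar1(J, sc.ld_rho)

    maf = rng.uniform(0.05, 0.5, size=J)
    het = 2.0 * maf * (1.0 - maf)
    gamma = np.sqrt((sc.target_r2 / J) / het) * rng.choice([-1.0, 1.0], size=J)

    alpha = np.zeros(J)
    n_invalid = math.ceil(sc.invalid_fraction * J)
    if n_invalid > 0 and sc.pleiotropy_mode != "none":
        invalid = rng.choice(J, size=n_invalid, replace=False)
        mean = sc.pleiotropy_mean if sc.pleiotropy_mode == "directional" else 0.0
        alpha[invalid] = rng.normal(mean, sc.pleiotropy_sd, size=n_invalid)
    # alpha is the direct effect of the exposure-RAISING allele (directional
    # pleiotropy is meaningful only in that orientation; the sign of gamma is
    # an arbitrary coding choice), so it enters through sign(gamma).
    big_gamma = sc.causal_effect * gamma + np.sign(gamma) * alpha

    se_x = 1.0 / np.sqrt(sc.n_exposure_sample * het)
    if sc.case_fraction is None:
        se_y = 1.0 / np.sqrt(sc.n_outcome_sample * het)
    else:
        k = sc.case_fraction
        se_y = 1.0 / np.sqrt(sc.n_outcome_sample * k * (1.0 - k) * het)

    if sc.ld_rho != 0.0:
        chol = np.linalg.cholesky(ld.r)
        noise_x = chol @ rng.standard_normal(J)
        noise_y = chol @ rng.standard_normal(J)
    else:
        noise_x = rng.standard_normal(J)
        noise_y = rng.standard_normal(J)
    gamma_hat = gamma + se_x * noise_x
    big_gamma_hat = big_gamma + se_y * noise_y

    alleles = [_NONPALINDROMIC_PAIRS[i] for i in rng.integers(len(_NONPALINDROMIC_PAIRS), size=J)]
    genes = [FUNCTIONAL_GENES[j % len(FUNCTIONAL_GENES)] for j in range(J)]

    exposure = _table(snp_ids, alleles, maf, gamma_hat, se_x, sc.n_exposure_sample,
                      "exposure", genes)
    outcome = _table(snp_ids, alleles, maf, big_gamma_hat, se_y, sc.n_outcome_sample,
                     "outcome")
    truth = SyntheticTruth(
        theta=sc.causal_effect,
        per_snp_gamma=gamma,
        per_snp_alpha=alpha,
        seed=sc.seed,
    )
    return exposure, outcome, ld, truth


def write_truth(truth: SyntheticTruth, snp_ids: Sequence[str], path: str) -> None:
    """TSV of per-SNP ground truth, with theta and seed on a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# theta={truth.theta!r} seed={truth.seed}\n")
        fh.write("snp_id\tgamma\talpha\n")
        for sid, g, a in zip(snp_ids, truth.per_snp_gamma, truth.per_snp_alpha):
            fh.write(f"{sid}\t{g!r}\t{a!r}\n")


def make_instrument_catalog(
    seed: int = 0,
    n_significant: int = 173,
    n_functional: int = 47,
    n_subthreshold: int = 20,
) -> list[SummaryAssociation]:
    """Synthetic stand-in for a published exposure-instrument table.

    The real supplementary instrument list is not redistributable here, so
    this generates a table with the same accounting structure: by default 173
    genome-wide significant SNPs (p < 5e-8), 47 of them annotated to the
    functional n-6 PUFA genes (FADS1/FADS2/NTAN1), plus sub-threshold filler
    rows.  Entirely synthetic — ids, effects, and p-values are drawn from the
    generator, not taken from any published table.
    """
    rng = np.random.default_rng(seed)
    out: list[SummaryAssociation] = []
    filler_genes = ("JMJD1C", "PDXDC1", "MYRF", "TMEM258")
    total = n_significant + n_subthreshold
    maf = rng.uniform(0.05, 0.5, size=total)
    for j in range(total):
        significant = j < n_significant
        if significant:
            z = rng.uniform(5.6, 30.0)  # p well below 5e-8
            gene = (FUNCTIONAL_GENES[j % 3] if j < n_functional
                    else filler_genes[j % len(filler_genes)])
        else:
            z = rng.uniform(1.0, 5.2)  # p above 5e-8
            gene = filler_genes[j % len(filler_genes)]
        se = 1.0 / math.sqrt(8631 * 2 * maf[j] * (1 - maf[j]))
        ea, oa = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]
        out.append(
            SummaryAssociation(
                snp_id=f"rs{900000 + j}",
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=float(z * se * rng.choice([-1.0, 1.0])),
                se=se,
                pvalue=float(_two_sided_p(np.array([z]))[0]),
                n=8631,
                trait="exposure",
                gene=gene,
            )
        )
    return out


def breakdown_sweep(
    base: SimulationScenario,
    fractions: Sequence[float],
    bias_tolerance: float = 0.05,
    seeds: int = 200,
    gamma: float = 2.0,
    maf: float = 0.25,
) -> float:
    """Locate the weighted-median estimator's invalid-weight breakdown point.

    The breakdown point is an asymptotic (noise-free) property, so the sweep
    uses constant-strength instruments — per-allele effect ``gamma`` at fixed
    MAF — which makes every IVW weight equal and the invalid WEIGHT share
    exactly the invalid count share, while outcome sampling noise at the
    scenario's sample size stays negligible next to the bias tolerance.  For
    each fraction, ``seeds`` replicates draw outcome associations with the
    invalid share carrying directional pleiotropy (mean
    ``base.pleiotropy_mean``); a fraction passes when the median absolute
    bias of the weighted median is at most ``bias_tolerance * |theta|``.
    Returns the largest passing fraction (0.0 if none pass).
    """
    if list(fractions) != sorted(fractions) or any(f >= 1 for f in fractions):
        raise ValidationError("fractions must be sorted ascending and < 1")
    J = base.n_snps
    theta = base.causal_effect
    alpha_mean = base.pleiotropy_mean
    het = 2.0 * maf * (1.0 - maf)
    if base.case_fraction is None:
        se_y = 1.0 / math.sqrt(base.n_outcome_sample * het)
    else:
        k = base.case_fraction
        se_y = 1.0 / math.sqrt(base.n_outcome_sample * k * (1.0 - k) * het)
    se_ratio = se_y / gamma
    weights = np.ones(J)
    largest = 0.0
    for fi, frac in enumerate(fractions):
        n_invalid = math.ceil(frac * J)
        biases = np.empty(seeds)
        for rep in range(seeds):
            rng = np.random.default_rng(np.random.SeedSequence([base.seed, fi, rep]))
            alpha = np.zeros(J)
            if n_invalid:
                idx = rng.choice(J, size=n_invalid, replace=False)
                alpha[idx] = rng.normal(alpha_mean, base.pleiotropy_sd, size=n_invalid)
            ratios = theta + alpha / gamma + rng.normal(0.0, se_ratio, size=J)
            biases[rep] = _weighted_median(ratios, weights) - theta
        if float(np.median(np.abs(biases))) <= bias_tolerance * abs(theta):
            largest = frac
    return largest
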