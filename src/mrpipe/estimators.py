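"""Causal-effect estimators and diagnostics for two-sample summary MR.

Implements the full battery reported in summary-data MR analyses:

* per-SNP Wald ratios with first-order (NOME) standard errors,
* inverse-variance weighting with fixed or multiplicative random effects,
  chosen by Cochran's Q heterogeneity test,
* the weighted-median estimator (consistent while valid instruments carry a
  majority of the weight) with a parametric-bootstrap SE,
* MR-Egger regression, whose intercept estimates average directional
  pleiotropy under the InSIDE assumption,
* PCA-based IVW for correlated instruments, which projects the weighted
  instrument system onto its leading principal components before generalized
  least squares, avoiding the numerical instability of inverting a full,
  possibly near-singular LD matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import EstimatorError
from .harmonize import HarmonizedInstrument, HarmonizedInstrumentSet
from .io import RunConfig

logger = logging.getLogger("mrpipe")

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class WaldEstimate:
    """One SNP's ratio estimate: outcome association over exposure association."""

    snp_id: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        assert self.se > 0

    @property
    def weight(self) -> float:
        return self.se ** -2


@dataclass
class MREstimate:
    """One estimator's result, with heterogeneity / pleiotropy diagnostics."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    model_variant: str = ""
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    n_components: Optional[int] = None
    outcome: str = ""
    snp_selection: str = ""
    binary_outcome: bool = False

    @property
    def ci_low(self) -> float:
        return self.beta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_95 * self.se


def _norm_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(inst: HarmonizedInstrument) -> WaldEstimate:
    """Ratio estimate for one SNP with the first-order delta-method SE.

    SE = se_outcome / |beta_exposure| treats the exposure association as known
    (NOME) — standard with strong instruments (F > 10).
    """
    if inst.beta_exposure == 0:
        raise EstimatorError("zero_instrument")
    return WaldEstimate(
        snp_id=inst.snp_id,
        ratio=inst.beta_outcome / inst.beta_exposure,
        se=inst.se_outcome / abs(inst.beta_exposure),
    )


def wald_ratio_second_order(inst: HarmonizedInstrument) -> WaldEstimate:
    """Ratio SE with the second-order delta term for exposure-side error."""
    if inst.beta_exposure == 0:
        raise EstimatorError("zero_instrument")
    ratio = inst.beta_outcome / inst.beta_exposure
    var = (inst.se_outcome ** 2 + ratio ** 2 * inst.se_exposure ** 2) / inst.beta_exposure ** 2
    return WaldEstimate(snp_id=inst.snp_id, ratio=ratio, se=float(np.sqrt(var)))


def cochran_q(walds: Sequence[WaldEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over the Wald ratios.

    Q = sum_j w_j (r_j - beta_hat)^2 with w_j = 1/se_j^2 and beta_hat the
    IVW pooled estimate; referred to chi-square with J-1 df.
    """
    if len(walds) < 2:
        raise EstimatorError("cochran_q requires at least 2 estimates")
    r = np.array([w.ratio for w in walds])
    w = np.array([w.weight for w in walds])
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    df = len(walds) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def ivw(
    walds: Sequence[WaldEstimate],
    heterogeneity_alpha: float = 0.05,
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    The point estimate (the precision-weighted mean) is identical under fixed
    and multiplicative random effects; when the Q test signals heterogeneity
    (p < ``heterogeneity_alpha``) the SE is inflated by sqrt(Q/(J-1)), floored
    at 1, and the variant is labelled ``ivw_random``.
    """
    if not walds:
        raise EstimatorError("ivw requires at least 1 estimate")
    r = np.array([w.ratio for w in walds])
    w = np.array([w.weight for w in walds])
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = df = qp = None
    variant = "ivw_fixed"
    if len(walds) >= 2:
        q, df, qp = cochran_q(walds)
        if qp < heterogeneity_alpha:
            variant = "ivw_random"
            se *= max(1.0, float(np.sqrt(q / df)))
    method = "ivw_random" if variant == "ivw_random" else "ivw_fixed"
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        pvalue=_norm_p(beta, se),
        n_snps=len(walds),
        model_variant=variant,
        q_stat=q,
        q_df=df,
        q_pvalue=qp,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the weight breakpoints.

    With standardized weights s_j (sorted by ratio), breakpoint
    p_j = sum_{i<j} s_i + s_j/2; the estimate interpolates the ordered ratios
    at p = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    s = weights[order] / np.sum(weights)
    p = np.cumsum(s) - s / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    walds: Sequence[WaldEstimate],
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Consistent even when up to 50% of the total weight comes from invalid
    instruments.  The SE is the SD of the estimate over ``bootstrap_reps``
    parametric resamples r_j* ~ N(r_j, se_j).
    """
    if len(walds) < 3:
        raise EstimatorError("too_few_instruments")
    # stable sort by (ratio, snp_id) for deterministic tie handling
    ordered = sorted(walds, key=lambda w: (w.ratio, w.snp_id))
    r = np.array([w.ratio for w in ordered])
    se = np.array([w.se for w in ordered])
    wt = np.array([w.weight for w in ordered])
    beta = _weighted_median(r, wt)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r, scale=se, size=(bootstrap_reps, len(r)))
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        boot[b] = _weighted_median(draws[b], wt)
    se_bm = float(np.std(boot, ddof=1))
    if se_bm <= 0:
        se_bm = float(np.finfo(float).tiny)
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se_bm,
        pvalue=_norm_p(beta, se_bm),
        n_snps=len(walds),
        model_variant="parametric_bootstrap",
    )


def mr_egger(instruments: HarmonizedInstrumentSet | Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: WLS of outcome on exposure associations with intercept.

    Instruments are first oriented so every exposure association is
    non-negative (negating both betas where needed), which makes the fit
    invariant to allele coding.  Weights are 1/se_outcome^2; SEs carry the
    multiplicative random-effects inflation max(1, residual scale).  The slope
    is the causal estimate (normal reference p); the intercept estimates the
    average directional pleiotropic effect and is tested against the t
    reference with J-2 df.
    """
    inst = list(instruments.instruments if isinstance(instruments, HarmonizedInstrumentSet) else instruments)
    if len(inst) < 3:
        raise EstimatorError("too_few_instruments")
    bx = np.array([i.beta_exposure for i in inst])
    by = np.array([i.beta_outcome for i in inst])
    sy = np.array([i.se_outcome for i in inst])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise EstimatorError("collinear")
    w = sy ** -2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ xtwy
    resid = by - X @ coef
    df = len(inst) - 2
    sigma2 = float(np.sum(w * resid ** 2) / df) if df > 0 else 0.0
    infl = max(1.0, float(np.sqrt(sigma2)))
    se_int, se_slope = np.sqrt(np.diag(cov_unscaled)) * infl
    intercept, slope = coef
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    return MREstimate(
        method="mr_egger",
        beta=float(slope),
        se=float(se_slope),
        pvalue=_norm_p(float(slope), float(se_slope)),
        n_snps=len(inst),
        model_variant="multiplicative_random" if infl > 1 else "fixed",
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=p_int,
    )


def pca_ivw(
    instruments: HarmonizedInstrumentSet,
    variance_kept: float = 0.99,
) -> MREstimate:
    """Generalized IVW on the leading principal components of the weighted
    instrument system — usable with many mutually correlated instruments.

    The matrix Psi with entries gamma_k gamma_l rho_kl / (s_k s_l)
    (gamma = exposure associations, s = outcome SEs, rho = LD) is
    eigendecomposed; the smallest number of leading components whose
    eigenvalue share reaches ``variance_kept`` is retained.  The projected
    system (gamma~, Gamma~, Sigma~) is then solved by GLS:
    beta = (gamma~' Sigma~^-1 gamma~)^-1 gamma~' Sigma~^-1 Gamma~.
    """
    if instruments.ld is None:
        raise EstimatorError("pca_ivw requires an LD matrix")
    inst = instruments.instruments
    if len(inst) < 2:
        raise EstimatorError("too_few_instruments")
    gamma = np.array([i.beta_exposure for i in inst])
    big_gamma = np.array([i.beta_outcome for i in inst])
    s = np.array([i.se_outcome for i in inst])
    rho = instruments.ld.r
    psi = np.outer(gamma / s, gamma / s) * rho
    vals, vecs = np.linalg.eigh(psi)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    vals = np.clip(vals, 0.0, None)
    total = float(np.sum(vals))
    if total <= 0:
        raise EstimatorError("singular_projection")
    share = np.cumsum(vals) / total
    m = int(np.searchsorted(share, variance_kept - 1e-12) + 1)
    P = vecs[:, :m]
    sigma = np.outer(s, s) * rho
    g_t = P.T @ gamma
    G_t = P.T @ big_gamma
    S_t = P.T @ sigma @ P
    try:
        sol_g = np.linalg.solve(S_t, g_t)
        sol_G = np.linalg.solve(S_t, G_t)
    except np.linalg.LinAlgError as exc:
        raise EstimatorError("singular_projection") from exc
    denom = float(g_t @ sol_g)
    if not np.isfinite(denom) or denom <= 0:
        raise EstimatorError("singular_projection")
    beta = float(g_t @ sol_G) / denom
    se = denom ** -0.5
    return MREstimate(
        method="pca_ivw",
        beta=beta,
        se=se,
        pvalue=_norm_p(beta, se),
        n_snps=len(inst),
        model_variant=f"components={m}",
        n_components=m,
    )


def estimate_all(
    instruments: HarmonizedInstrumentSet,
    config: RunConfig,
) -> tuple[list[MREstimate], list[tuple[str, str]]]:
    """Run every estimator the instrument count and inputs permit.

    Returns the estimates plus an explicit list of (method, reason) for
    estimators that could not run — nothing is silently absent.
    """
    if len(instruments) < 1:
        raise EstimatorError("no instruments")
    skipped: list[tuple[str, str]] = []
    usable = []
    for i in instruments.instruments:
        if i.beta_exposure == 0:
            logger.warning("estimate_all: %s has zero exposure association; excluded", i.snp_id)
        else:
            usable.append(i)
    walds = [wald_ratio(i) for i in usable]
    estimates: list[MREstimate] = []
    if walds:
        estimates.append(ivw(walds, config.heterogeneity_alpha))
    else:
        skipped.append(("ivw", "no_usable_instruments"))
    if len(walds) >= 3:
        estimates.append(weighted_median(walds, config.wm_bootstrap_reps, config.rng_seed))
        estimates.append(mr_egger(usable))
    else:
        skipped.append(("weighted_median", "too_few_instruments"))
        skipped.append(("mr_egger", "too_few_instruments"))
    if instruments.ld is not None and len(instruments) >= 2:
        try:
            estimates.append(pca_ivw(instruments, config.pca_variance_kept))
        except EstimatorError as exc:
            skipped.append(("pca_ivw", str(exc)))
    else:
        skipped.append(("pca_ivw", "no_ld_matrix" if instruments.ld is None else "too_few_instruments"))
    for method, reason in skipped:
        logger.info("estimate_all: %s skipped [reason=%s]", method, reason)
    return estimates, skipped
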