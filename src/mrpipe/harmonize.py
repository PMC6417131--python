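"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires each SNP's exposure and outcome associations to refer
to the same effect allele.  Matching is done on allele letters, falling back
to strand complements; palindromic variants (A/T, C/G), whose strand cannot be
resolved from letters, are oriented by effect-allele frequency or dropped when
the frequency sits too close to 0.5 to discriminate.

Sign convention for LD: the input r matrix is signed with respect to the
outcome table's allele coding.  When a SNP's outcome association is flipped
onto the exposure orientation, its off-diagonal r entries are negated
(``D r D`` with D = diag(+/-1)), which is required for PCA-IVW correctness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import PipelineError
from .io import LDMatrix, RunConfig, SummaryAssociation

logger = logging.getLogger("mrpipe")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(a: str, b: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return _COMPLEMENT[a] == b


@dataclass(frozen=True)
class Drop:
    """A SNP removed from the analysis, with its reason code."""

    snp_id: str
    reason: str


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome associations on a common effect-allele orientation."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None
    flipped: bool = False
    proxy_for: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.se_exposure > 0 and self.se_outcome > 0
        if self.proxy_for is not None:
            assert self.proxy_r2 is not None and self.proxy_r2 >= 0.8


@dataclass
class HarmonizedInstrumentSet:
    instruments: list[HarmonizedInstrument]
    ld: Optional[LDMatrix] = None
    dropped: list[Drop] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise PipelineError("duplicate snp_id in harmonized set")
        if self.ld is not None and len(self.ld.snp_ids) != len(ids):
            raise PipelineError("LD dimension does not match instrument count")

    def __len__(self) -> int:
        return len(self.instruments)


def _frequency_flip(eaf_exposure: float, eaf_outcome: float) -> bool:
    """True when frequencies agree only under allele swap (1 - eaf)."""
    return abs(eaf_outcome - eaf_exposure) > abs((1.0 - eaf_outcome) - eaf_exposure)


def align_alleles(
    exposure: SummaryAssociation,
    outcome: SummaryAssociation,
    eaf_window: float = 0.08,
) -> HarmonizedInstrument | Drop:
    """Orient one outcome association onto the exposure's effect allele.

    Direct letter match copies; swapped letters negate the outcome beta and
    reflect its frequency; a match under strand complement is complemented
    first.  Palindromic SNPs are oriented by frequency agreement, and dropped
    as ``ambiguous_palindrome`` when either frequency is missing or lies
    within ``0.5 +/- eaf_window``.
    """
    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return Drop(exposure.snp_id, "allele_mismatch")
        if exposure.eaf is None or outcome.eaf is None:
            return Drop(exposure.snp_id, "ambiguous_palindrome")
        if abs(exposure.eaf - 0.5) <= eaf_window or abs(outcome.eaf - 0.5) <= eaf_window:
            return Drop(exposure.snp_id, "ambiguous_palindrome")
        flipped = _frequency_flip(exposure.eaf, outcome.eaf)
    else:
        if (o_ea, o_oa) == (e_ea, e_oa):
            flipped = False
        elif (o_ea, o_oa) == (e_oa, e_ea):
            flipped = True
        else:
            c_ea, c_oa = complement(o_ea), complement(o_oa)
            if (c_ea, c_oa) == (e_ea, e_oa):
                flipped = False
            elif (c_ea, c_oa) == (e_oa, e_ea):
                flipped = True
            else:
                return Drop(exposure.snp_id, "allele_mismatch")

    beta_out = -outcome.beta if flipped else outcome.beta
    eaf_out = None
    if outcome.eaf is not None:
        eaf_out = 1.0 - outcome.eaf if flipped else outcome.eaf
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=e_ea,
        other_allele=e_oa,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
        flipped=flipped,
    )


def substitute_proxy(
    missing_snp: str,
    candidates: Sequence[tuple[str, float]],
    outcome_table: Sequence[SummaryAssociation],
    r2_min: float = 0.8,
) -> Optional[tuple[str, float]]:
    """Pick the best available proxy for an outcome-missing SNP.

    Returns the candidate with maximal r^2 among those present in the outcome
    table with r^2 >= ``r2_min`` (ties broken by snp id for determinism), or
    None when no candidate qualifies — a valid, logged outcome.
    """
    present = {a.snp_id for a in outcome_table}
    eligible = [(sid, r2) for sid, r2 in candidates if sid in present and r2 >= r2_min]
    if not eligible:
        return None
    return max(eligible, key=lambda t: (t[1], t[0]))


def _proxy_instrument(
    exposure: SummaryAssociation,
    proxy_assoc: SummaryAssociation,
    r2: float,
    eaf_window: float,
) -> HarmonizedInstrument | Drop:
    # The proxy keeps its own alleles; orientation relative to the index SNP
    # can only come from frequency agreement.
    if exposure.eaf is None or proxy_assoc.eaf is None:
        return Drop(exposure.snp_id, "proxy_unorientable")
    if abs(exposure.eaf - 0.5) <= eaf_window or abs(proxy_assoc.eaf - 0.5) <= eaf_window:
        return Drop(exposure.snp_id, "proxy_unorientable")
    flipped = _frequency_flip(exposure.eaf, proxy_assoc.eaf)
    beta_out = -proxy_assoc.beta if flipped else proxy_assoc.beta
    eaf_out = 1.0 - proxy_assoc.eaf if flipped else proxy_assoc.eaf
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=proxy_assoc.se,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
        flipped=flipped,
        proxy_for=proxy_assoc.snp_id,
        proxy_r2=r2,
    )


def harmonize_set(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    ld: Optional[LDMatrix],
    config: RunConfig,
    proxies: Optional[dict[str, Sequence[tuple[str, float]]]] = None,
) -> HarmonizedInstrumentSet:
    """Harmonize every exposure SNP against the outcome table.

    Every exposure SNP ends up matched, proxied, or dropped with a reason
    code.  The LD matrix is restricted to retained SNPs and sign-adjusted
    (``D r D``) for flipped instruments.  Raises ``PipelineError`` when zero
    instruments survive.
    """
    if not exposure:
        raise PipelineError("no_instruments")
    outcome_by_id = {}
    for a in outcome:
        outcome_by_id.setdefault(a.snp_id, a)

    instruments: list[HarmonizedInstrument] = []
    dropped: list[Drop] = []
    seen: set[str] = set()
    for exp in exposure:
        if exp.snp_id in seen:
            dropped.append(Drop(exp.snp_id, "duplicate"))
            continue
        seen.add(exp.snp_id)
        out = outcome_by_id.get(exp.snp_id)
        if out is not None:
            res = align_alleles(exp, out, config.palindromic_eaf_window)
        elif proxies and exp.snp_id in proxies:
            sub = substitute_proxy(exp.snp_id, proxies[exp.snp_id], outcome, config.proxy_r2_min)
            if sub is None:
                res = Drop(exp.snp_id, "missing_in_outcome")
            else:
                proxy_id, r2 = sub
                res = _proxy_instrument(exp, outcome_by_id[proxy_id], r2, config.palindromic_eaf_window)
        else:
            res = Drop(exp.snp_id, "missing_in_outcome")
        if isinstance(res, Drop):
            dropped.append(res)
            logger.info("harmonize: dropped %s [reason=%s]", res.snp_id, res.reason)
        else:
            instruments.append(res)

    if not instruments:
        raise PipelineError("no_instruments")

    ld_sub = None
    if ld is not None:
        kept = [i.snp_id for i in instruments if i.snp_id in set(ld.snp_ids)]
        if len(kept) == len(instruments):
            ld_sub = ld.subset([i.snp_id for i in instruments])
            ld_sub = ld_sub.sign_flip([i.flipped for i in instruments])
        else:
            missing = [i.snp_id for i in instruments if i.snp_id not in set(ld.snp_ids)]
            logger.warning(
                "harmonize: LD matrix lacks %d retained SNPs (%s...); discarding LD",
                len(missing), missing[0],
            )
    return HarmonizedInstrumentSet(instruments=instruments, ld=ld_sub, dropped=dropped)
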