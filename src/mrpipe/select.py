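"""Instrument screens: significance, gene annotation, top-k uncorrelated
selection, instrument strength, confounder screen, and static exclusions.

Each screen partitions its input into kept and dropped SNPs (with reason
codes), so the pipeline's accounting of instruments is complete at every
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io import LDMatrix, SummaryAssociation

logger = logging.getLogger("mrpipe")


@dataclass
class SelectionResult:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (snp_id, reason)
    selection_label: str = ""

    def __post_init__(self) -> None:
        k = set(self.kept)
        d = {s for s, _ in self.dropped}
        if k & d:
            raise ValidationError(f"selection kept and dropped overlap: {sorted(k & d)[:3]}")

    @property
    def dropped_ids(self) -> list[str]:
        return [s for s, _ in self.dropped]


def filter_genome_wide(
    assocs: Sequence[SummaryAssociation], p_threshold: float = 5e-8
) -> SelectionResult:
    """Keep SNPs strictly below the genome-wide significance threshold."""
    kept, dropped = [], []
    for a in assocs:
        if a.pvalue < p_threshold:
            kept.append(a.snp_id)
        else:
            dropped.append((a.snp_id, "not_genome_wide_significant"))
    return SelectionResult(kept, dropped, "all_gws")


def filter_gene_annotation(
    assocs: Sequence[SummaryAssociation], genes: Iterable[str]
) -> SelectionResult:
    """Keep SNPs annotated to one of the given genes (case-insensitive).

    Used to restrict to variants in genes functionally relevant to the
    exposure's metabolism (for n-6 PUFA: the FADS1/FADS2 desaturases and
    their regulator NTAN1).
    """
    gene_set = {g.upper() for g in genes}
    kept, dropped = [], []
    for a in assocs:
        if a.gene is None:
            raise ValidationError(f"{a.snp_id}: gene annotation missing")
        if a.gene.upper() in gene_set:
            kept.append(a.snp_id)
        else:
            dropped.append((a.snp_id, "outside_functional_genes"))
    return SelectionResult(kept, dropped, "functional")


def select_top_uncorrelated(
    assocs: Sequence[SummaryAssociation],
    ld: LDMatrix,
    k: int = 3,
    r2_max: float = 0.1,
) -> SelectionResult:
    """Greedy most-significant-k selection subject to pairwise r^2 <= r2_max.

    SNPs are ranked by ascending p-value (ties broken lexicographically by
    id, so the output is invariant to input row order); each is accepted iff
    its r^2 with every already-accepted SNP does not exceed ``r2_max``.  If
    fewer than k acceptable SNPs exist the shorter list is returned with a
    logged warning.
    """
    ranked = sorted(assocs, key=lambda a: (a.pvalue, a.snp_id))
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for a in ranked:
        if len(kept) >= k:
            dropped.append((a.snp_id, "beyond_top_k"))
            continue
        if any(ld.r_between(a.snp_id, b) ** 2 > r2_max for b in kept):
            dropped.append((a.snp_id, "correlated_with_selected"))
            continue
        kept.append(a.snp_id)
    if len(kept) < k:
        logger.warning("select_top_uncorrelated: only %d of %d requested SNPs found", len(kept), k)
    return SelectionResult(kept, dropped, "top_uncorrelated")


def f_statistic(assoc: SummaryAssociation) -> float:
    """Per-SNP instrument strength, the squared z-score (beta/se)^2.

    This is the standard summary-data approximation to the first-stage F;
    values above 10 conventionally mark a strong instrument.
    """
    return (assoc.beta / assoc.se) ** 2


def f_statistic_from_r2(r2: float, n: int) -> float:
    """Alternative F approximation from variance explained: R^2 (n-2) / (1-R^2)."""
    if not (0 <= r2 < 1):
        raise ValidationError(f"r2 {r2} outside [0, 1)")
    return r2 * (n - 2) / (1.0 - r2)


def filter_f_statistic(
    assocs: Sequence[SummaryAssociation], f_cutoff: float = 10.0
) -> SelectionResult:
    """Drop weak instruments (F <= cutoff)."""
    kept, dropped = [], []
    for a in assocs:
        if f_statistic(a) > f_cutoff:
            kept.append(a.snp_id)
        else:
            dropped.append((a.snp_id, "weak_instrument"))
    return SelectionResult(kept, dropped, "strong")


def screen_confounders(pvals: pd.DataFrame, alpha: float = 0.05) -> SelectionResult:
    """Bonferroni-corrected confounder screen.

    ``pvals`` is a SNP x confounder table of association p-values.  The
    threshold divides alpha by the total number of tests (SNPs x confounders,
    the most conservative denominator); a SNP with any p-value below it is
    dropped as potentially confounded.
    """
    n_tests = pvals.shape[0] * pvals.shape[1]
    threshold = alpha / n_tests
    kept, dropped = [], []
    for snp, row in pvals.iterrows():
        if (row < threshold).any():
            dropped.append((str(snp), "confounder_associated"))
        else:
            kept.append(str(snp))
    logger.info(
        "confounder screen: threshold %.4g (%d tests), dropped %d of %d SNPs",
        threshold, n_tests, len(dropped), pvals.shape[0],
    )
    return SelectionResult(kept, dropped, "confounder_screen")


def apply_exclusions(
    assocs: Sequence[SummaryAssociation],
    exclusion_list: Iterable[str],
    exclude: bool = True,
) -> SelectionResult:
    """Remove SNPs with known direct outcome associations (static lists).

    With ``exclude=False`` the list is only logged and everything is kept —
    the mode used when the excluded variants may lie on the causal pathway.
    """
    excl = set(exclusion_list)
    kept, dropped = [], []
    for a in assocs:
        if exclude and a.snp_id in excl:
            dropped.append((a.snp_id, "direct_outcome_association"))
        else:
            kept.append(a.snp_id)
    if not exclude and excl:
        flagged = sorted({a.snp_id for a in assocs} & excl)
        logger.info("exclusion list retained (pass-through): %d flagged SNPs kept", len(flagged))
    return SelectionResult(kept, dropped, "exclusions")


def subset_assocs(
    assocs: Sequence[SummaryAssociation], keep: Iterable[str]
) -> list[SummaryAssociation]:
    """Restrict an association list to the given ids, preserving order."""
    keep_set = set(keep)
    return [a for a in assocs if a.snp_id in keep_set]
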