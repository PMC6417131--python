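"""Reading, validating and writing the tabular formats the pipeline touches.

GWAS summary-association tables arrive as whitespace/tab-delimited text with a
header; column names vary wildly between consortia, so the caller supplies an
explicit column map instead of relying on auto-sniffing.  LD matrices arrive as
a SNP-id header line followed by a square numeric body.  The run configuration
collects every threshold the analysis uses so that a single object (loadable
from YAML) fully determines a run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger("mrpipe")

VALID_ALLELES = frozenset("ACGT")

#: standard field name -> default column name in the file
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
    "gene": "gene",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

_TINY_P = 5e-324  # smallest positive float; p-values of exactly 0 are clipped here


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait in one sample.

    ``beta`` is on the trait's reporting scale: per % of total fatty acids for
    the exposure, log-odds for binary outcomes, SD units for transformed
    continuous outcomes.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None
    trait: str = ""
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases in A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")


@dataclass
class LDMatrix:
    """Symmetric SNP x SNP correlation matrix (r, not r^2) with named rows.

    Signs follow the allele coding of the outcome summary table (see
    :mod:`mrpipe.harmonize`); r^2-based operations are coding-free.
    """

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {n} SNP ids"
            )
        if len(set(self.snp_ids)) != n:
            raise ValidationError("duplicate SNP ids in LD matrix")

    @classmethod
    def from_array(
        cls,
        snp_ids: Sequence[str],
        r: np.ndarray,
        *,
        asym_tol: float = 1e-6,
        psd_tol: float = 1e-8,
    ) -> "LDMatrix":
        """Validate, symmetrize, and (if needed) PSD-project a raw matrix.

        Published r matrices are commonly rounded to a few decimals, which can
        push the smallest eigenvalue slightly negative; eigenvalue clipping at
        zero followed by re-normalization to unit diagonal restores a valid
        correlation matrix and is logged as a warning.
        """
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise FormatError(f"LD matrix body is not square: shape {r.shape}")
        asym = np.max(np.abs(r - r.T)) if r.size else 0.0
        if asym > asym_tol:
            raise ValidationError(f"LD matrix asymmetric beyond tolerance: max |r-r'| = {asym:g}")
        r = (r + r.T) / 2.0
        if r.size and np.max(np.abs(np.diag(r) - 1.0)) > 1e-6:
            raise ValidationError("LD matrix diagonal deviates from 1 beyond 1e-6")
        np.fill_diagonal(r, 1.0)
        if r.size:
            w = np.linalg.eigvalsh(r)
            if w[0] < -psd_tol:
                logger.warning(
                    "LD matrix not PSD (min eigenvalue %.3g); projecting by eigenvalue clipping",
                    w[0],
                )
                vals, vecs = np.linalg.eigh(r)
                vals = np.clip(vals, 0.0, None)
                r = (vecs * vals) @ vecs.T
                d = np.sqrt(np.clip(np.diag(r), 1e-12, None))
                r = r / np.outer(d, d)
                np.fill_diagonal(r, 1.0)
        return cls(list(snp_ids), r)

    def index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index(s) for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def sign_flip(self, flipped: Sequence[bool]) -> "LDMatrix":
        """Return D r D with D = diag(-1 where flipped else +1)."""
        d = np.where(np.asarray(flipped, dtype=bool), -1.0, 1.0)
        return LDMatrix(list(self.snp_ids), d[:, None] * self.r * d[None, :])


@dataclass
class RunConfig:
    """All thresholds of the analysis in one place.

    Defaults follow the published screening rules where one exists
    (p < 5e-8 significance, F > 10 instrument strength, proxy r^2 >= 0.8,
    heterogeneity alpha 0.05); the remainder are the package's documented
    choices.
    """

    p_threshold: float = 5e-8
    f_cutoff: float = 10.0
    proxy_r2_min: float = 0.8
    heterogeneity_alpha: float = 0.05
    pca_variance_kept: float = 0.99
    wm_bootstrap_reps: int = 1000
    rng_seed: int = 0
    palindromic_eaf_window: float = 0.08
    uncorrelated_r2_max: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_threshold", "proxy_r2_min", "heterogeneity_alpha",
                     "pca_variance_kept", "palindromic_eaf_window", "uncorrelated_r2_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"config field {name}={v} must lie in (0, 1)")
        if self.wm_bootstrap_reps < 1:
            raise ValidationError("wm_bootstrap_reps must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers


def read_summary_table(
    path: str,
    column_map: Optional[Mapping[str, str]] = None,
    trait: str = "",
) -> list[SummaryAssociation]:
    """Read a whitespace/tab-delimited GWAS summary table.

    ``column_map`` maps standard field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the column names in the file; omitted
    optional fields (eaf, n, gene) are treated as absent.  Rows with missing
    beta or se, or with non-biallelic/non-ACGT allele codes, are dropped with a
    logged count; an se <= 0 is a hard validation error naming the row.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype={cmap["snp_id"]: str})
    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[fld]!r} (for {fld})")

    out: list[SummaryAssociation] = []
    n_missing = 0
    n_nonbiallelic = 0
    n_pclip = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        rowno = pos + 2  # header is line 1
        rec = {fld: getattr(row, cmap[fld]) for fld in MANDATORY_FIELDS}
        if pd.isna(rec["beta"]) or pd.isna(rec["se"]):
            n_missing += 1
            continue
        if float(rec["se"]) <= 0:
            raise ValidationError(f"{path} row {rowno}: se = {rec['se']} is not positive")
        ea = str(rec["effect_allele"]).upper()
        oa = str(rec["other_allele"]).upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            n_nonbiallelic += 1
            continue
        p = float(rec["pvalue"])
        if p == 0.0:
            p = _TINY_P
            n_pclip += 1
        eaf = None
        if cmap["eaf"] in df.columns and not pd.isna(getattr(row, cmap["eaf"])):
            eaf = float(getattr(row, cmap["eaf"]))
        n = None
        if cmap["n"] in df.columns and not pd.isna(getattr(row, cmap["n"])):
            n = int(getattr(row, cmap["n"]))
        gene = None
        if cmap["gene"] in df.columns and not pd.isna(getattr(row, cmap["gene"])):
            gene = str(getattr(row, cmap["gene"]))
        out.append(
            SummaryAssociation(
                snp_id=str(rec["snp_id"]),
                effect_allele=ea,
                other_allele=oa,
                beta=float(rec["beta"]),
                se=float(rec["se"]),
                pvalue=p,
                eaf=eaf,
                n=n,
                trait=trait,
                gene=gene,
            )
        )
    if n_missing:
        logger.info("%s: dropped %d rows with missing beta/se [reason=missing_stats]", path, n_missing)
    if n_nonbiallelic:
        logger.info("%s: dropped %d non-biallelic/indel rows [reason=non_biallelic]", path, n_nonbiallelic)
    if n_pclip:
        logger.warning("%s: clipped %d zero p-values to smallest positive float", path, n_pclip)
    return out


def read_ld_matrix(path: str) -> LDMatrix:
    """Read an LD matrix: first line SNP ids, body a square numeric matrix."""
    with open(path) as fh:
        header = fh.readline().split()
        rows = [line.split() for line in fh if line.strip()]
    if not header:
        raise FormatError(f"{path}: empty LD matrix file")
    try:
        body = np.array([[float(x) for x in row] for row in rows], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric LD matrix body ({exc})") from exc
    if body.ndim != 2 or body.shape != (len(header), len(header)):
        raise FormatError(
            f"{path}: LD body shape {body.shape} does not match {len(header)} header ids"
        )
    return LDMatrix.from_array(header, body)


def read_exclusion_list(path: str) -> set[str]:
    """One SNP id per line; '#' starts a comment."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def read_confounder_table(path: str) -> pd.DataFrame:
    """SNP x confounder p-value table (TSV, snp ids in the first column)."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: confounder p-value table has missing cells")
    return df


# ---------------------------------------------------------------------------
# writers


def write_summary_table(assocs: Sequence[SummaryAssociation], path: str) -> None:
    """Write associations back out in the canonical column order."""
    df = pd.DataFrame(
        {
            "snp": [a.snp_id for a in assocs],
            "effect_allele": [a.effect_allele for a in assocs],
            "other_allele": [a.other_allele for a in assocs],
            "eaf": [a.eaf if a.eaf is not None else np.nan for a in assocs],
            "beta": [a.beta for a in assocs],
            "se": [a.se for a in assocs],
            "pvalue": [a.pvalue for a in assocs],
            "n": [a.n if a.n is not None else np.nan for a in assocs],
            "gene": [a.gene if a.gene is not None else "" for a in assocs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _fmt(x: Optional[float], nd: Optional[int] = None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if nd is not None:
        return f"{x:.{nd}f}"
    return f"{x:.3g}"


REPORT_COLUMNS = [
    "outcome", "snp_selection", "method", "n_snps", "estimate", "or",
    "ci_low", "ci_high", "pvalue", "q_stat", "q_pvalue", "model_variant",
    "egger_intercept", "egger_intercept_p",
]


def write_report(estimates: Sequence, path: str) -> None:
    """Write estimator results as a tab-delimited report.

    One row per estimate, in input order.  Binary outcomes additionally get an
    odds-ratio column (exp of the log-odds estimate, 3 decimals, matching how
    case-control MR results are conventionally tabulated); other numbers are
    printed at 3 significant figures.
    """
    if not estimates:
        raise ValidationError("write_report: empty estimate list")
    lines = ["\t".join(REPORT_COLUMNS)]
    for e in estimates:
        odds = math.exp(e.beta) if e.binary_outcome else None
        lines.append(
            "\t".join(
                [
                    e.outcome,
                    e.snp_selection,
                    e.method,
                    str(e.n_snps),
                    _fmt(e.beta),
                    _fmt(odds, nd=3),
                    _fmt(e.ci_low),
                    _fmt(e.ci_high),
                    _fmt(e.pvalue),
                    _fmt(e.q_stat),
                    _fmt(e.q_pvalue),
                    e.model_variant,
                    _fmt(e.egger_intercept),
                    _fmt(e.egger_intercept_p),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
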