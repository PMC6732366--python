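"""Reading ranked gene association lists and SNP-level preprocessing.

Gene-level inputs are (symbol, p-value) tables from any upstream GWAS or
differential-expression analysis.  SNP-level inputs can be reduced to a
gene-level list via the standard quality filters (minor allele frequency,
Hardy-Weinberg equilibrium) followed by a min-p within-window aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GENE_SOURCES = ("GWAS", "GEP", "OTHER")


@dataclass(frozen=True)
class GeneAssociation:
    gene: str
    p_value: float
    source: str = "OTHER"

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value for {self.gene} outside (0, 1]: {self.p_value}")
        if self.source not in GENE_SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class RankRecord:
    gene: str
    score: float
    rank: int


@dataclass
class RankedList:
    """Genes ordered by a score (raw p-value or HA), ranks 1..N.

    Ranks are dense integers consistent with non-decreasing score order;
    gene symbols are unique.
    """

    records: list[RankRecord]
    score_kind: str  # "P_VALUE" or "HA"

    def __post_init__(self):
        if self.score_kind not in ("P_VALUE", "HA"):
            raise ValidationError(f"unknown score_kind {self.score_kind!r}")
        n = len(self.records)
        if [r.rank for r in self.records] != list(range(1, n + 1)):
            raise ValidationError("ranks must be the dense sequence 1..N in order")
        scores = [r.score for r in self.records]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValidationError("scores must be non-decreasing with rank")
        genes = [r.gene for r in self.records]
        if len(set(genes)) != n:
            raise ValidationError("duplicate gene symbols in ranked list")

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list[str]:
        return [r.gene for r in self.records]

    def rank_of(self) -> dict[str, int]:
        return {r.gene: r.rank for r in self.records}


def rank_by_pvalue(associations: Sequence[GeneAssociation]) -> RankedList:
    """Order a gene list by ascending p-value (ties broken by symbol)."""
    ordered = sorted(associations, key=lambda a: (a.p_value, a.gene))
    return RankedList(
        records=[RankRecord(a.gene, a.p_value, i) for i, a in enumerate(ordered, 1)],
        score_kind="P_VALUE",
    )


def read_gene_list(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    source: str = "OTHER",
) -> list[GeneAssociation]:
    """Read a (gene, p) TSV.

    Rows with p outside (0, 1] are rejected with row-level warnings; duplicate
    genes collapse to the minimum p (logged).  No parseable rows is a hard
    error.
    """
    cols = {"gene": "gene", "p": "p"}
    if dialect:
        cols.update(dialect)
    path = Path(path)
    if not path.exists():
        raise IOError(f"gene list not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    for key, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}' (for {key})")

    best: dict[str, float] = {}
    n_bad = n_dup = 0
    for i, (gene, p) in enumerate(zip(df[cols["gene"]], df[cols["p"]]), start=2):
        gene = str(gene).strip().upper()
        try:
            p = float(p)
        except (TypeError, ValueError):
            p = float("nan")
        if not gene or not (0.0 < p <= 1.0):
            n_bad += 1
            logger.warning("%s row %d: rejected (gene=%r, p=%r)", path, i, gene, p)
            continue
        if gene in best:
            n_dup += 1
            best[gene] = min(best[gene], p)
        else:
            best[gene] = p
    if n_dup:
        logger.warning("%s: %d duplicate gene rows collapsed to min p", path, n_dup)
    if not best:
        raise FormatError(f"{path}: no parseable gene rows")
    return [GeneAssociation(g, p, source) for g, p in best.items()]


def write_gene_list(associations: Iterable[GeneAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.gene, a.p_value) for a in associations], columns=["gene", "p"]
    )
    df.to_csv(path, sep="\t", index=False)


# --- SNP-level preprocessing -------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int
    genotype_counts: tuple[int, int, int]  # (n_AA, n_Aa, n_aa)
    assoc_p: float | None = None

    def __post_init__(self):
        if any(c < 0 for c in self.genotype_counts):
            raise ValidationError(f"{self.snp_id}: negative genotype count")
        if sum(self.genotype_counts) == 0:
            raise ValidationError(f"{self.snp_id}: genotype counts sum to zero")


@dataclass(frozen=True)
class GeneModel:
    """1-based inclusive gene coordinates used for SNP assignment."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: start > end")


def minor_allele_frequency(counts: tuple[int, int, int]) -> float:
    """Frequency of the rarer allele from genotype counts; in [0, 0.5]."""
    n_aa, n_ab, n_bb = counts
    total = n_aa + n_ab + n_bb
    if total <= 0:
        raise ValidationError("genotype counts sum to zero")
    f = (2 * n_bb + n_ab) / (2 * total)
    return min(f, 1.0 - f)


def hwe_test(counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
    proportions p^2, 2pq, q^2 at the observed allele frequency.

    Monomorphic input returns p = 1 by convention.
    """
    n_aa, n_ab, n_bb = counts
    total = n_aa + n_ab + n_bb
    if total <= 0:
        raise ValidationError("genotype counts sum to zero")
    q = (2 * n_bb + n_ab) / (2 * total)
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * total
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(sps.chi2.sf(stat, df=1))


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_failed_maf: int = 0
    n_failed_hwe: int = 0
    maf_min: float = 0.05
    hwe_p_min: float = 0.001

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_snps(
    records: Sequence[SnpRecord],
    maf_min: float = 0.05,
    hwe_p_min: float = 0.001,
) -> tuple[list[SnpRecord], FilterReport]:
    """Keep SNPs with MAF > ``maf_min`` and HWE p >= ``hwe_p_min``.

    The HWE criterion excludes markers that violate equilibrium (small p),
    the conventional direction for a genotyping-quality filter.  Returns the
    kept records plus a per-criterion report; a SNP failing both counts in
    both tallies.
    """
    report = FilterReport(n_input=len(records), maf_min=maf_min, hwe_p_min=hwe_p_min)
    kept: list[SnpRecord] = []
    for rec in records:
        ok_maf = minor_allele_frequency(rec.genotype_counts) > maf_min
        ok_hwe = hwe_test(rec.genotype_counts) >= hwe_p_min
        if not ok_maf:
            report.n_failed_maf += 1
        if not ok_hwe:
            report.n_failed_hwe += 1
        if ok_maf and ok_hwe:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def snp_to_gene(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    window_bp: int = 50_000,
    source: str = "GWAS",
) -> list[GeneAssociation]:
    """Aggregate SNP p-values to genes: minimum p over SNPs falling within
    [start - window, end + window] on the same chromosome.

    A SNP inside several (overlapping) windows is assigned to every such
    gene.  Genes with no assigned SNP are absent from the output.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    missing = [s.snp_id for s in snps if s.assoc_p is None]
    if missing:
        raise ValidationError(f"SNPs without assoc_p: {missing[:5]}")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    best: dict[str, float] = {}
    for s in snps:
        for g in by_chrom.get(s.chrom, ()):
            if g.start - window_bp <= s.pos <= g.end + window_bp:
                key = g.gene.strip().upper()
                if key not in best or s.assoc_p < best[key]:
                    best[key] = s.assoc_p
    return [GeneAssociation(g, p, source) for g, p in sorted(best.items())]


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """SNP table TSV: snp, chrom, pos, n_AA, n_Aa, n_aa[, p]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["snp", "chrom", "pos", "n_AA", "n_Aa", "n_aa"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    has_p = "p" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SnpRecord(
                snp_id=str(row.snp),
                chrom=str(row.chrom),
                pos=int(row.pos),
                genotype_counts=(int(row.n_AA), int(row.n_Aa), int(row.n_aa)),
                assoc_p=float(row.p) if has_p else None,
            )
        )
    return out


def read_gene_models(path: str | Path, zero_based: bool = False) -> list[GeneModel]:
    """Gene models as BED-like TSV (chrom, start, end, gene).

    This artifact's dialect is 1-based inclusive; pass ``zero_based=True``
    for half-open BED input (converted and logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    if zero_based:
        logger.info("%s: converting 0-based half-open coordinates to 1-based inclusive", path)
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start) + (1 if zero_based else 0)
        out.append(GeneModel(gene=str(row.gene), chrom=str(row.chrom), start=start, end=int(row.end)))
    return out
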