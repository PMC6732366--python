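"""The HPO-Shuffle re-ranking score and rank-change bookkeeping.

For a gene with association p-value P and m phenotype terms shared with the
disease-specific repository (HPR), the HPO-associated value is

    HA = P / (m + 1)

so that HA = P exactly when the gene has no relevant phenotype annotation,
and genes with many relevant annotations are pulled toward the top of the
list.  Lists are re-ordered by ascending HA; smaller means more strongly
associated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .ingest import GeneAssociation, RankRecord, RankedList
from .ontology import GenePhenotypeMap, PhenotypeRepository


@dataclass(frozen=True)
class HAScore:
    gene: str
    p_value: float
    matched_terms: int
    ha: float

    def __post_init__(self):
        if self.ha != self.p_value / (self.matched_terms + 1):
            raise ValidationError(f"{self.gene}: ha != p/(m+1)")


@dataclass(frozen=True)
class RankChange:
    """Signed rank movement; positive delta = moved toward rank 1."""

    gene: str
    rank_before: int
    rank_after: int

    @property
    def delta(self) -> int:
        return self.rank_before - self.rank_after


def count_relevant_terms(
    gene: str,
    gene_map: GenePhenotypeMap,
    hpr: PhenotypeRepository,
    count_mode: str = "intersection",
) -> int:
    """Number of the gene's phenotype terms that fall in the repository.

    ``count_mode='intersection'`` (default) counts only HPR-matching terms;
    ``'all'`` counts the gene's full annotation set whenever at least one
    term matches (an alternative reading of the scoring rule, kept behind a
    flag).  Genes absent from the map count 0.
    """
    terms = gene_map.terms_for(gene)
    matched = terms & hpr.term_ids
    if count_mode == "intersection":
        return len(matched)
    if count_mode == "all":
        return len(terms) if matched else 0
    raise ValidationError(f"unknown count_mode {count_mode!r}")


def ha_score(p_value: float, matched_terms: int) -> float:
    """HA = p / (m + 1); the +1 keeps unannotated genes at their raw p."""
    if not (0.0 < p_value <= 1.0):
        raise ValidationError(f"p-value outside (0, 1]: {p_value}")
    if matched_terms < 0:
        raise ValidationError(f"negative matched_terms: {matched_terms}")
    return p_value / (matched_terms + 1)


def rerank(
    associations: Sequence[GeneAssociation],
    gene_map: GenePhenotypeMap,
    hpr: PhenotypeRepository,
    count_mode: str = "intersection",
) -> tuple[RankedList, list[HAScore]]:
    """Re-rank a gene list by ascending HA.

    Ties break on ascending raw p-value, then gene symbol, so output is
    deterministic.  Duplicate input genes are an error (collapse upstream).
    """
    if not associations:
        raise ValidationError("empty gene list")
    genes = [a.gene for a in associations]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate genes in input: {dupes[:5]}")

    scores = [
        HAScore(
            gene=a.gene,
            p_value=a.p_value,
            matched_terms=(m := count_relevant_terms(a.gene, gene_map, hpr, count_mode)),
            ha=ha_score(a.p_value, m),
        )
        for a in associations
    ]
    ordered = sorted(scores, key=lambda s: (s.ha, s.p_value, s.gene))
    ranked = RankedList(
        records=[RankRecord(s.gene, s.ha, i) for i, s in enumerate(ordered, 1)],
        score_kind="HA",
    )
    return ranked, ordered


def rank_changes(before: RankedList, after: RankedList) -> list[RankChange]:
    """Per-gene before/after rank deltas; the two lists must cover the same
    genes (symmetric difference reported otherwise)."""
    b = before.rank_of()
    a = after.rank_of()
    if b.keys() != a.keys():
        diff = sorted(set(b) ^ set(a))
        raise ValidationError(f"gene sets differ; symmetric difference: {diff[:10]}")
    return [RankChange(g, b[g], a[g]) for g in before.genes()]


def write_reranked_tsv(
    path: str | Path, ranked: RankedList, scores: Sequence[HAScore]
) -> None:
    by_gene = {s.gene: s for s in scores}
    rows = [
        (r.rank, r.gene, by_gene[r.gene].p_value, by_gene[r.gene].matched_terms, r.score)
        for r in ranked.records
    ]
    pd.DataFrame(rows, columns=["rank", "gene", "p_value", "matched_terms", "ha"]).to_csv(
        path, sep="\t", index=False
    )


def write_rank_changes_tsv(path: str | Path, changes: Sequence[RankChange]) -> None:
    rows = [(c.gene, c.rank_before, c.rank_after, c.delta) for c in changes]
    pd.DataFrame(rows, columns=["gene", "rank_before", "rank_after", "delta"]).to_csv(
        path, sep="\t", index=False
    )
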