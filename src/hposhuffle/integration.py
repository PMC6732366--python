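"""Top-fraction selection, list intersection and hypergeometric enrichment.

Two re-ranked lists (e.g. GWAS and expression-profiling) are reduced to
their top fraction, intersected, and the intersection is tested for
enrichment of known disease genes with the exact hypergeometric tail.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom

from .errors import ValidationError
from .ingest import RankedList


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test of drawing ``sample_k`` known disease genes in a
    set of ``sample_n``, from a universe of ``population_n`` genes containing
    ``population_k`` known ones."""

    population_n: int
    population_k: int
    sample_n: int
    sample_k: int
    p_value: float
    tail: str = "UPPER"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "population_n": self.population_n,
                "population_k": self.population_k,
                "sample_n": self.sample_n,
                "sample_k": self.sample_k,
                "p_value": self.p_value,
                "tail": self.tail,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def top_fraction(ranked: RankedList, q: float, rounding: str = "floor") -> set[str]:
    """Genes in the top fraction ``q`` of a ranked list.

    The cutoff is floor(q*N) by default (matching published set sizes for
    q = 0.75); ``rounding='ceil'`` guarantees a non-empty result for any
    q > 0 and is kept for rounding-sensitivity studies.
    """
    if not (0.0 < q <= 1.0):
        raise ValidationError(f"fraction q outside (0, 1]: {q}")
    if rounding not in ("floor", "ceil"):
        raise ValidationError(f"unknown rounding {rounding!r}")
    n = len(ranked)
    cutoff = math.floor(q * n) if rounding == "floor" else math.ceil(q * n)
    return {r.gene for r in ranked.records if r.rank <= cutoff}


def intersect_sets(a: Iterable[str], b: Iterable[str]) -> set[str]:
    """Set intersection after symbol canonicalisation (uppercase, strip)."""
    canon = lambda s: {str(g).strip().upper() for g in s}
    return canon(a) & canon(b)


def hypergeom_enrichment(
    population_n: int,
    population_k: int,
    sample_n: int,
    sample_k: int,
    inclusive: bool = True,
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment p-value.

    ``inclusive=True`` (default) gives P(X >= k), the conventional
    enrichment tail, which is 1 at k = 0.  ``inclusive=False`` gives the
    strictly-greater tail P(X > k) — the convention of R's ``phyper(k, ...,
    lower.tail=FALSE)`` without the usual k-1 adjustment, which some
    published tables follow.  Tail masses are accumulated in log space by
    the backend, so magnitudes far below double-precision underflow of a
    naive product are representable.
    """
    if not (0 <= population_k <= population_n):
        raise ValidationError("need 0 <= population_k <= population_n")
    if not (0 <= sample_n <= population_n):
        raise ValidationError("need 0 <= sample_n <= population_n")
    if not (0 <= sample_k <= min(sample_n, population_k)):
        raise ValidationError("need 0 <= sample_k <= min(sample_n, population_k)")
    threshold = sample_k - 1 if inclusive else sample_k
    p = float(hypergeom.sf(threshold, population_n, population_k, sample_n))
    return EnrichmentResult(population_n, population_k, sample_n, sample_k, p)


def read_gene_set(path: str | Path) -> set[str]:
    """One gene symbol per line; canonicalised to uppercase."""
    return {
        ln.strip().upper()
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    }


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted({str(g).strip().upper() for g in genes})))
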