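"""Ontology parsing and construction of the disease-specific phenotype repository.

The Human Phenotype Ontology (HPO) links phenotypic abnormality terms to
diseases and genes.  This module reads the OBO flat file and two annotation
tables (disease -> phenotype and gene -> phenotype) and builds the Human
Phenotype Repository (HPR): the union of phenotype terms annotated to a
selected family of diseases, optionally extended with ontology ancestors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import CycleError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Accession pattern for phenotype term identifiers ("HP:" + 7 digits).
HP_ACCESSION = re.compile(r"^HP:\d{7}$")


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    parent_ids: frozenset[str]
    obsolete: bool = False

    def __post_init__(self):
        if self.term_id in self.parent_ids:
            raise ValidationError(f"term {self.term_id} lists itself as a parent")


@dataclass
class OntologyGraph:
    """Directed acyclic graph of ontology terms (child -> parent is_a links)."""

    terms: dict[str, OntologyTerm]
    root_ids: frozenset[str]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> set[str]:
        """All strict ancestors of ``term_id``, skipping obsolete terms."""
        seen: set[str] = set()
        stack = list(self.terms[term_id].parent_ids)
        while stack:
            t = stack.pop()
            if t in seen or t not in self.terms:
                continue
            if self.terms[t].obsolete:
                continue
            seen.add(t)
            stack.extend(self.terms[t].parent_ids)
        return seen


@dataclass(frozen=True)
class DiseasePhenotypeAnnotation:
    disease_id: str
    disease_name: str
    term_id: str

    def __post_init__(self):
        if not (self.disease_id and self.disease_name and self.term_id):
            raise ValidationError("disease annotation fields must be non-empty")


@dataclass(frozen=True)
class PhenotypeRepository:
    """The HPR: phenotype terms linked to the selected disease family."""

    term_ids: frozenset[str]
    source_disease_ids: frozenset[str]
    closure_applied: bool = False

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.term_ids

    def __len__(self) -> int:
        return len(self.term_ids)


@dataclass
class GenePhenotypeMap:
    """gene symbol (canonical uppercase) -> set of phenotype term accessions."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.entries.get(gene.strip().upper(), frozenset())

    def __len__(self) -> int:
        return len(self.entries)


def _scan_stanza_ids(path: Path) -> None:
    # Cheap pre-pass: every [Term] stanza must carry an id tag; report the
    # stanza's opening line on violation (the OBO reader is silent about this).
    stanza_line = None
    has_id = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("["):
                if stanza_line is not None and not has_id:
                    raise FormatError(f"{path}: [Term] stanza at line {stanza_line} has no id tag")
                stanza_line = lineno if stripped == "[Term]" else None
                has_id = False
            elif stanza_line is not None and stripped.startswith("id:"):
                has_id = True
    if stanza_line is not None and not has_id:
        raise FormatError(f"{path}: [Term] stanza at line {stanza_line} has no id tag")


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Obsolete terms are retained but flagged; ``is_a`` targets become parent
    links.  A cyclic ``is_a`` chain raises :class:`CycleError` listing the
    cycle.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"ontology file not found: {path}")
    _scan_stanza_ids(path)
    g = obonet.read_obo(str(path), ignore_obsolete=False)

    terms: dict[str, OntologyTerm] = {}
    isa = nx.DiGraph()
    for node, data in g.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset(
            v for _, v, key in g.out_edges(node, keys=True) if key == "is_a"
        )
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", ""),
            parent_ids=parents,
            obsolete=obsolete,
        )
        isa.add_node(node)
        for p in parents:
            isa.add_edge(node, p)

    if not nx.is_directed_acyclic_graph(isa):
        cycle = [u for u, _ in nx.find_cycle(isa)]
        raise CycleError(cycle)

    roots = frozenset(
        t.term_id
        for t in terms.values()
        if not t.obsolete and not (t.parent_ids & terms.keys())
    )
    return OntologyGraph(terms=terms, root_ids=roots)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def load_disease_annotations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[DiseasePhenotypeAnnotation]:
    """Read a disease -> phenotype annotation TSV (HPOA-style dialect).

    ``dialect`` maps the logical keys ``disease_id``, ``disease_name`` and
    ``term_id`` onto column names; defaults follow the HPOA convention
    (``database_id``, ``disease_name``, ``hpo_id``).  Rows with a malformed
    accession are collected as row-level errors and skipped; if every row is
    bad a :class:`FormatError` is raised.
    """
    cols = {"disease_id": "database_id", "disease_name": "disease_name", "term_id": "hpo_id"}
    if dialect:
        cols.update(dialect)
    df = _read_table(path)
    for key, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}' (for {key})")

    records: list[DiseasePhenotypeAnnotation] = []
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data row
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        term = str(row[cols["term_id"]]).strip()
        if not HP_ACCESSION.match(term):
            bad_rows.append(f"row {i}: bad accession {term!r}")
            continue
        records.append(
            DiseasePhenotypeAnnotation(
                disease_id=str(row[cols["disease_id"]]).strip(),
                disease_name=str(row[cols["disease_name"]]).strip(),
                term_id=term,
            )
        )
    if bad_rows:
        logger.warning("%s: %d malformed rows skipped (%s ...)", path, len(bad_rows), bad_rows[0])
    if len(df) > 0 and not records:
        raise FormatError(f"{path}: no valid annotation rows ({'; '.join(bad_rows[:5])})")
    return records


def load_gene_phenotype_map(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> GenePhenotypeMap:
    """Read a gene -> phenotype TSV into a :class:`GenePhenotypeMap`.

    Gene symbols are canonicalised (uppercased, whitespace-stripped) and
    duplicate (gene, term) pairs collapse under set semantics.
    """
    cols = {"gene": "gene_symbol", "term_id": "hpo_id"}
    if dialect:
        cols.update(dialect)
    df = _read_table(path)
    for key, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}' (for {key})")

    entries: dict[str, set[str]] = {}
    bad_rows: list[str] = []
    for i, (gene, term) in enumerate(zip(df[cols["gene"]], df[cols["term_id"]]), start=2):
        gene = str(gene).strip().upper()
        term = str(term).strip()
        if not gene or not HP_ACCESSION.match(term):
            bad_rows.append(f"row {i}")
            continue
        entries.setdefault(gene, set()).add(term)
    if bad_rows:
        logger.warning("%s: %d malformed rows skipped", path, len(bad_rows))
    if len(df) > 0 and not entries:
        raise FormatError(f"{path}: no valid gene-annotation rows")
    return GenePhenotypeMap(entries={g: frozenset(ts) for g, ts in entries.items()})


# --- disease selectors -------------------------------------------------------

Selector = Callable[[DiseasePhenotypeAnnotation], bool]


def name_contains(substring: str) -> Selector:
    """Select diseases whose name contains ``substring`` (case-insensitive)."""
    needle = substring.upper()

    def _sel(a: DiseasePhenotypeAnnotation) -> bool:
        return needle in a.disease_name.upper()

    return _sel


def ids_in(disease_ids: Iterable[str]) -> Selector:
    wanted = {str(d) for d in disease_ids}
    return lambda a: a.disease_id in wanted


def select_all(_: DiseasePhenotypeAnnotation) -> bool:
    return True


def ancestor_closure(graph: OntologyGraph, term_ids: Iterable[str]) -> set[str]:
    """Input terms plus all strict ancestors, excluding ontology roots.

    Terms absent from the graph are kept unchanged (warned).  Obsolete terms
    are dropped from the closure.  Idempotent.
    """
    out: set[str] = set()
    for t in term_ids:
        if t not in graph:
            logger.warning("term %s not in ontology; kept without ancestors", t)
            out.add(t)
            continue
        if graph.terms[t].obsolete:
            logger.warning("obsolete term %s excluded from closure", t)
            continue
        out.add(t)
        out.update(a for a in graph.ancestors(t) if a not in graph.root_ids)
    return out


def build_hpr(
    annotations: Iterable[DiseasePhenotypeAnnotation],
    selector: Selector = select_all,
    graph: OntologyGraph | None = None,
    apply_closure: bool = False,
) -> PhenotypeRepository:
    """Build the phenotype repository for the diseases picked by ``selector``.

    With ``apply_closure`` the term set is extended by ontology ancestors
    (roots excluded), which requires ``graph``.
    """
    if apply_closure and graph is None:
        raise ValidationError("apply_closure requires an ontology graph")
    selected = [a for a in annotations if selector(a)]
    term_ids = {a.term_id for a in selected}
    disease_ids = {a.disease_id for a in selected}
    if apply_closure:
        term_ids = ancestor_closure(graph, term_ids)
    return PhenotypeRepository(
        term_ids=frozenset(term_ids),
        source_disease_ids=frozenset(disease_ids),
        closure_applied=apply_closure,
    )


def write_hpr(hpr: PhenotypeRepository, path: str | Path) -> None:
    """Serialise the repository as one term id per line (sorted)."""
    Path(path).write_text("".join(f"{t}\n" for t in sorted(hpr.term_ids)))


def read_hpr(path: str | Path) -> PhenotypeRepository:
    terms = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return PhenotypeRepository(
        term_ids=frozenset(terms), source_disease_ids=frozenset(), closure_applied=False
    )
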