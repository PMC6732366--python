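"""Weighted co-expression module detection and CMap signature export.

The core follows the standard weighted-network recipe: a soft-thresholded
adjacency from pairwise gene correlations, a topological overlap measure
(TOM) of shared neighbourhood, average-linkage hierarchical clustering of
1 - TOM with a static cut, and per-module eigengene / trait association.
Directional up/down gene sets of selected modules are written in GRP format
(one symbol per line) for querying the Connectivity Map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, pearsonr

from .errors import ValidationError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ExpressionMatrix:
    """genes x samples expression values with a binary sample trait."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    trait: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.trait = np.asarray(self.trait, dtype=int)
        n_g, n_s = self.values.shape
        if len(self.genes) != n_g or len(self.samples) != n_s:
            raise ValidationError("matrix shape does not match gene/sample labels")
        if len(set(self.genes)) != n_g:
            raise ValidationError("duplicate gene symbols")
        if len(set(self.samples)) != n_s:
            raise ValidationError("duplicate sample ids")
        if self.trait.size != n_s:
            raise ValidationError("trait length must equal sample count")
        if not set(np.unique(self.trait)) <= {0, 1}:
            raise ValidationError("trait must be binary 0/1")
        if np.any(self.values.std(axis=1) == 0):
            bad = [g for g, s in zip(self.genes, self.values.std(axis=1)) if s == 0]
            raise ValidationError(f"zero-variance gene rows: {bad[:5]}")

    def standardized(self) -> np.ndarray:
        v = self.values
        return (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)


@dataclass(frozen=True)
class ModuleStats:
    size: int
    trait_correlation: float
    p_value: float


@dataclass
class ModuleAssignment:
    labels: dict[str, str]
    module_stats: dict[str, ModuleStats] = field(default_factory=dict)

    def module_genes(self, name: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == name]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out


@dataclass(frozen=True)
class CmapSignature:
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self):
        if self.up & self.down:
            raise ValidationError(f"up/down overlap: {sorted(self.up & self.down)[:5]}")


def load_expression(
    matrix_path: str | Path, trait_path: str | Path
) -> ExpressionMatrix:
    """Expression TSV/CSV (first column = gene symbol, columns = samples)
    plus a two-column sample/trait table."""
    matrix_path = Path(matrix_path)
    sep = "," if matrix_path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    traits = pd.read_csv(trait_path, sep="\t", index_col=0).iloc[:, 0]
    missing = [s for s in df.columns if s not in traits.index]
    if missing:
        raise ValidationError(f"samples without trait values: {missing[:5]}")
    return ExpressionMatrix(
        genes=[str(g).strip().upper() for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        trait=traits.loc[df.columns].to_numpy(dtype=int),
    )


def _check_square_unit_diag(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{what} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError(f"{what} must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValidationError(f"{what} must have unit diagonal")
    return m


def soft_adjacency(
    correlations: np.ndarray, beta: int, signed: bool = False
) -> np.ndarray:
    """Soft-threshold a correlation matrix into adjacency weights in [0, 1].

    Unsigned: a_ij = |cor_ij|^beta.  Signed: a_ij = ((1 + cor_ij)/2)^beta,
    which maps anti-correlation to 0 instead of folding it onto 1.
    """
    if beta < 1:
        raise ValidationError(f"beta must be >= 1, got {beta}")
    cor = _check_square_unit_diag(correlations, "correlation matrix")
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a weighted network.

    Bins the connectivity distribution and regresses log10 frequency on
    log10 mean connectivity; returns (signed R^2, slope).  The R^2 is
    negated when the slope is positive, so only decaying distributions can
    reach a high fit index.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    k = k[k > 0]
    if k.size < 3:
        return 0.0, 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    keep = (counts > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0, 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    fit = linregress(x, y)
    r2 = float(fit.rvalue**2)
    return (r2 if fit.slope < 0 else -r2), float(fit.slope)


def pick_beta(
    correlations: np.ndarray,
    candidate_betas: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple[int, pd.DataFrame, bool]:
    """Smallest soft-threshold power reaching the scale-free fit target.

    Returns (beta, fit table, warned); when no candidate reaches the target
    the maximal-fit beta is returned with ``warned=True``.
    """
    if not candidate_betas:
        raise ValidationError("need at least one candidate beta")
    rows = []
    for beta in candidate_betas:
        r2, slope = scale_free_fit(soft_adjacency(correlations, beta, signed=signed))
        rows.append((beta, r2, slope))
    table = pd.DataFrame(rows, columns=["beta", "signed_r2", "slope"])
    passing = table[table.signed_r2 >= r2_target]
    if len(passing):
        return int(passing.beta.iloc[0]), table, False
    best = int(table.loc[table.signed_r2.idxmax(), "beta"])
    logger.warning(
        "no candidate beta reached scale-free fit %.2f; falling back to beta=%d", r2_target, best
    )
    return best, table, True


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: similarity of two genes' weighted neighbourhoods.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity of i.
    Diagonal is 1; output is symmetric and bounded in [0, 1].
    """
    a = _check_square_unit_diag(adjacency, "adjacency matrix")
    if np.any(a < 0) or np.any(a > 1 + 1e-12):
        raise ValidationError("adjacency values must lie in [0, 1]")
    k = a.sum(axis=0) - 1.0  # unit diagonal excluded
    shared = a @ a - 2.0 * a  # removes the u=i and u=j terms (a_ii = a_jj = 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def cluster_modules(
    tom: np.ndarray,
    genes: Sequence[str],
    min_module_size: int = 10,
    cut_height: float = 0.25,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_module_size`` are relabelled "unassigned"; module
    names M1, M2, ... are assigned by descending size (ties by first gene
    position), so the labelling is deterministic and independent of input
    gene order.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    tom = np.asarray(tom, dtype=float)
    if tom.shape[0] != len(genes):
        raise ValidationError("TOM size does not match gene list")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    # order by (-size, position of first member sorted by gene symbol)
    order = sorted(
        (c for c, idx in clusters.items() if len(idx) >= min_module_size),
        key=lambda c: (-len(clusters[c]), min(str(genes[i]) for i in clusters[c])),
    )
    labels = {str(g): UNASSIGNED for g in genes}
    for name_i, c in enumerate(order, start=1):
        for i in clusters[c]:
            labels[str(genes[i])] = f"M{name_i}"
    return ModuleAssignment(labels=labels)


def _eigengene(z_sub: np.ndarray) -> np.ndarray:
    """First principal component across samples of a standardized gene-row
    submatrix, sign-oriented to align with mean module expression."""
    if z_sub.shape[0] == 1:
        return z_sub[0]
    _, _, vt = np.linalg.svd(z_sub, full_matrices=False)
    eg = vt[0]
    if np.corrcoef(eg, z_sub.mean(axis=0))[0, 1] < 0:
        eg = -eg
    return eg


def module_trait_association(
    matrix: ExpressionMatrix, assignment: ModuleAssignment
) -> ModuleAssignment:
    """Fill per-module eigengene/trait statistics.

    For each module the eigengene (first PC of the standardized submatrix)
    is correlated with the binary trait; the p-value is the two-sided
    correlation t-test.  The "unassigned" pool gets no statistics.
    """
    missing = [g for g in matrix.genes if g not in assignment.labels]
    if missing:
        raise ValidationError(f"genes without module label: {missing[:5]}")
    z = matrix.standardized()
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    stats: dict[str, ModuleStats] = {}
    for name in sorted(set(assignment.labels.values())):
        if name == UNASSIGNED:
            continue
        idx = [gene_idx[g] for g in assignment.module_genes(name) if g in gene_idx]
        eg = _eigengene(z[idx])
        r, p = pearsonr(eg, matrix.trait)
        stats[name] = ModuleStats(size=len(idx), trait_correlation=float(r), p_value=float(p))
    return ModuleAssignment(labels=dict(assignment.labels), module_stats=stats)


def split_up_down(
    matrix: ExpressionMatrix,
    assignment: ModuleAssignment,
    selected_modules: Sequence[str],
) -> CmapSignature:
    """Partition pooled module genes by the sign of the standardized
    case-vs-control mean difference; zero-difference genes are dropped."""
    known = set(assignment.labels.values())
    bad = [m for m in selected_modules if m not in known]
    if bad:
        raise ValidationError(f"unknown modules: {bad}")
    pool = [g for m in selected_modules for g in assignment.module_genes(m)]
    z = matrix.standardized()
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}
    case = matrix.trait == 1
    ctrl = ~case
    up, down = set(), set()
    for g in pool:
        d = z[gene_idx[g], case].mean() - z[gene_idx[g], ctrl].mean()
        if d > 0:
            up.add(g)
        elif d < 0:
            down.add(g)
        else:
            logger.warning("gene %s has zero case/control difference; dropped", g)
    return CmapSignature(up=frozenset(up), down=frozenset(down))


def write_grp(signature: CmapSignature, up_path: str | Path, down_path: str | Path) -> None:
    """GRP export: one uppercase symbol per line, sorted, newline-terminated.
    Both sets must be non-empty and disjoint at export time."""
    if not signature.up or not signature.down:
        raise ValidationError("up and down sets must both be non-empty at export")
    for genes, path in ((signature.up, up_path), (signature.down, down_path)):
        Path(path).write_text("".join(f"{g.upper()}\n" for g in sorted(genes)))


def read_grp(path: str | Path) -> set[str]:
    return {ln.strip().upper() for ln in Path(path).read_text().splitlines() if ln.strip()}


def write_module_tables(
    assignment: ModuleAssignment, labels_path: str | Path, stats_path: str | Path
) -> None:
    pd.DataFrame(
        sorted(assignment.labels.items()), columns=["gene", "module"]
    ).to_csv(labels_path, sep="\t", index=False)
    payload = {
        name: {"size": s.size, "trait_correlation": s.trait_correlation, "p_value": s.p_value}
        for name, s in sorted(assignment.module_stats.items())
    }
    Path(stats_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
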