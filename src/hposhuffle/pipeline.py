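"""End-to-end orchestration: re-ranking, integration, modules, CMap export.

The pipeline mirrors the three-step strategy the package implements:
(1) build the disease phenotype repository and re-rank the GWAS and
expression gene lists by HA score; (2) intersect the top fractions and test
known-gene enrichment; (3) detect co-expression modules, associate them
with the sample trait and export directional GRP signatures.  Every stage
writes plain-text artifacts; a manifest records SHA-256 checksums, and a
completed stage with unchanged inputs is skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coexpression as cx
from . import integration as integ
from . import ontology as onto
from .rerank import (
    rank_changes,
    rerank as rerank_by_ha,
    write_rank_changes_tsv,
    write_reranked_tsv,
)
from . import stats as st
from .errors import HpoShuffleError, StageError, ValidationError
from .ingest import rank_by_pvalue, read_gene_list

logger = logging.getLogger(__name__)

STAGES = ("build_hpr", "rerank", "evaluate", "integrate", "modules", "export_cmap")


@dataclass
class PipelineConfig:
    """Flat, file-serialisable configuration of a pipeline run."""

    # inputs
    gwas_list: str = ""
    gep_list: str = ""
    gene_annotations: str = ""
    disease_annotations: str = ""
    obo: str = ""  # optional; required only with apply_closure
    known_genes: str = ""  # optional; enables evaluation + enrichment
    expression: str = ""
    trait: str = ""
    # HPR options
    disease_name_substring: str = ""  # empty = select all diseases
    apply_closure: bool = False
    # re-ranking
    count_mode: str = "intersection"
    # integration
    q: float = 0.75
    rounding: str = "floor"
    universe_size: int = 0  # 0 = size of the union of the two input lists
    # modules
    beta_candidates: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 8, 10, 12])
    r2_target: float = 0.8
    signed_network: bool = False
    cut_height: float = 0.9
    min_module_size: int = 10
    module_p_threshold: float = 0.05
    # misc
    seed: int = 0
    n_perm: int = 1999
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0.0 < self.q <= 1.0):
            raise ValidationError(f"q outside (0, 1]: {self.q}")
        if self.apply_closure and not self.obo:
            raise ValidationError("apply_closure requires an obo path")
        for name in ("gwas_list", "gep_list", "gene_annotations", "disease_annotations"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ValidationError(f"missing input {name}: {p!r}")
        for name in ("known_genes", "expression", "trait", "obo"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ValidationError(f"input {name} does not exist: {p!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True, default_flow_style=False)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_fingerprint(inputs: list[Path], params: dict) -> str:
    h = hashlib.sha256()
    for p in sorted(inputs, key=str):
        h.update(str(p).encode())
        h.update(_sha256(p).encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()


class _Runner:
    """Tracks stage state so completed stages with unchanged inputs skip."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.state_path = outdir / ".stages.json"
        self.state = (
            json.loads(self.state_path.read_text()) if self.state_path.exists() else {}
        )

    def run(self, stage: str, inputs: list[Path], params: dict, outputs: list[Path], fn):
        fp = _stage_fingerprint(inputs, params)
        if self.state.get(stage) == fp and all(o.exists() for o in outputs):
            logger.info("stage %s: up to date, skipped", stage)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except HpoShuffleError as exc:
            raise StageError(stage, str(exc)) from exc
        missing = [o for o in outputs if not o.exists()]
        if missing:
            raise StageError(stage, f"expected outputs missing: {missing}")
        self.state[stage] = fp
        self.state_path.write_text(json.dumps(self.state, indent=2, sort_keys=True))
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages into ``outdir`` and write the artifact manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.yaml")
    runner = _Runner(outdir)

    # -- stage 1: phenotype repository ---------------------------------------
    hpr_path = outdir / "hpr.txt"

    def _build_hpr():
        annotations = onto.load_disease_annotations(config.disease_annotations)
        selector = (
            onto.name_contains(config.disease_name_substring)
            if config.disease_name_substring
            else onto.select_all
        )
        graph = onto.parse_obo(config.obo) if config.apply_closure else None
        hpr = onto.build_hpr(annotations, selector, graph, config.apply_closure)
        if not hpr.term_ids:
            raise ValidationError("selector matched no disease annotations")
        onto.write_hpr(hpr, hpr_path)

    hpr_inputs = [Path(config.disease_annotations)] + (
        [Path(config.obo)] if config.apply_closure else []
    )
    runner.run(
        "build_hpr",
        hpr_inputs,
        {"substring": config.disease_name_substring, "closure": config.apply_closure},
        [hpr_path],
        _build_hpr,
    )

    # -- stage 2: re-ranking ---------------------------------------------------
    reranked = {s: outdir / f"reranked_{s.lower()}.tsv" for s in ("GWAS", "GEP")}

    def _rerank():
        hpr = onto.read_hpr(hpr_path)
        gene_map = onto.load_gene_phenotype_map(config.gene_annotations)
        for source, in_path in (("GWAS", config.gwas_list), ("GEP", config.gep_list)):
            assoc = read_gene_list(in_path, source=source)
            ranked, scores = rerank_by_ha(assoc, gene_map, hpr, config.count_mode)
            write_reranked_tsv(reranked[source], ranked, scores)

    runner.run(
        "rerank",
        [hpr_path, Path(config.gene_annotations), Path(config.gwas_list), Path(config.gep_list)],
        {"count_mode": config.count_mode},
        list(reranked.values()),
        _rerank,
    )

    # -- stage 3: evaluation ---------------------------------------------------
    change_paths = {s: outdir / f"rank_changes_{s.lower()}.tsv" for s in ("GWAS", "GEP")}
    eval_path = outdir / "evaluation.json"

    def _evaluate():
        known = integ.read_gene_set(config.known_genes) if config.known_genes else set()
        report = {}
        for source, in_path in (("GWAS", config.gwas_list), ("GEP", config.gep_list)):
            assoc = read_gene_list(in_path, source=source)
            before = rank_by_pvalue(assoc)
            after_df = _read_ranked(reranked[source])
            changes = rank_changes(before, after_df)
            write_rank_changes_tsv(change_paths[source], changes)
            summary = st.rank_shift_summary(changes)
            entry = {
                "n_up": summary.n_up,
                "n_down": summary.n_down,
                "n_same": summary.n_same,
                "max_up": summary.max_up,
                "max_down": summary.max_down,
            }
            if known:
                deltas_known = [c.delta for c in changes if c.gene in known]
                deltas_other = [c.delta for c in changes if c.gene not in known]
                if deltas_known and deltas_other:
                    test = st.wilcoxon_rank_sum(deltas_known, deltas_other)
                    entry["wilcoxon_known_vs_other"] = json.loads(test.to_json())
            report[source] = entry
        eval_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    runner.run(
        "evaluate",
        [Path(config.gwas_list), Path(config.gep_list)]
        + list(reranked.values())
        + ([Path(config.known_genes)] if config.known_genes else []),
        {},
        list(change_paths.values()) + [eval_path],
        _evaluate,
    )

    # -- stage 4: integration --------------------------------------------------
    intersection_path = outdir / "intersection.txt"
    enrichment_path = outdir / "enrichment.json"

    def _integrate():
        top = {}
        sizes = {}
        for source in ("GWAS", "GEP"):
            ranked = _read_ranked(reranked[source])
            sizes[source] = len(ranked)
            top[source] = integ.top_fraction(ranked, config.q, config.rounding)
        shared = integ.intersect_sets(top["GWAS"], top["GEP"])
        integ.write_gene_set(shared, intersection_path)
        payload = {"q": config.q, "n_gwas_top": len(top["GWAS"]), "n_gep_top": len(top["GEP"]),
                   "n_intersection": len(shared)}
        if config.known_genes:
            known = integ.read_gene_set(config.known_genes)
            universe = config.universe_size or len(
                set(_read_ranked(reranked["GWAS"]).genes())
                | set(_read_ranked(reranked["GEP"]).genes())
            )
            res = integ.hypergeom_enrichment(
                universe, len(known & _universe_cap(known, universe)),
                len(shared), len(shared & known),
            )
            payload["enrichment"] = json.loads(res.to_json())
        enrichment_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    runner.run(
        "integrate",
        list(reranked.values())
        + ([Path(config.known_genes)] if config.known_genes else []),
        {"q": config.q, "rounding": config.rounding, "universe": config.universe_size},
        [intersection_path, enrichment_path],
        _integrate,
    )

    manifest_artifacts = [
        hpr_path, *reranked.values(), *change_paths.values(), eval_path,
        intersection_path, enrichment_path,
    ]

    # -- stages 5+6: modules and CMap export (optional inputs) ------------------
    if config.expression and config.trait:
        modules_path = outdir / "modules.tsv"
        stats_path = outdir / "module_stats.json"
        up_path = outdir / "up.grp"
        down_path = outdir / "down.grp"

        def _modules():
            matrix = cx.load_expression(config.expression, config.trait)
            cor = _corrcoef(matrix)
            beta, table, warned = cx.pick_beta(
                cor, config.beta_candidates, config.r2_target, config.signed_network
            )
            table.to_csv(outdir / "beta_fit.tsv", sep="\t", index=False)
            adjacency = cx.soft_adjacency(cor, beta, signed=config.signed_network)
            tom = cx.tom_similarity(adjacency)
            assignment = cx.cluster_modules(
                tom, matrix.genes, config.min_module_size, config.cut_height
            )
            assignment = cx.module_trait_association(matrix, assignment)
            cx.write_module_tables(assignment, modules_path, stats_path)

        runner.run(
            "modules",
            [Path(config.expression), Path(config.trait)],
            {
                "betas": config.beta_candidates,
                "r2": config.r2_target,
                "signed": config.signed_network,
                "cut": config.cut_height,
                "min_size": config.min_module_size,
            },
            [modules_path, stats_path],
            _modules,
        )

        def _export():
            matrix = cx.load_expression(config.expression, config.trait)
            labels = _read_labels(modules_path)
            stats = json.loads(stats_path.read_text())
            selected = sorted(
                (m for m, s in stats.items() if s["p_value"] < config.module_p_threshold),
                key=lambda m: stats[m]["p_value"],
            )
            if not selected:
                raise ValidationError(
                    f"no module passes p < {config.module_p_threshold}; nothing to export"
                )
            assignment = cx.ModuleAssignment(labels=labels)
            signature = cx.split_up_down(matrix, assignment, selected)
            cx.write_grp(signature, up_path, down_path)

        runner.run(
            "export_cmap",
            [modules_path, stats_path, Path(config.expression), Path(config.trait)],
            {"p_threshold": config.module_p_threshold},
            [up_path, down_path],
            _export,
        )
        manifest_artifacts += [modules_path, stats_path, up_path, down_path]

    manifest = {p.name: _sha256(p) for p in manifest_artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _universe_cap(known: set[str], universe: int) -> set[str]:
    # the known set cannot exceed the declared universe
    if len(known) > universe:
        raise ValidationError("known gene set larger than declared universe")
    return known


def _read_ranked(path: Path):
    import pandas as pd

    from .ingest import RankRecord, RankedList

    df = pd.read_csv(path, sep="\t")
    return RankedList(
        records=[
            RankRecord(str(g), float(s), int(r))
            for r, g, s in zip(df["rank"], df["gene"], df["ha"])
        ],
        score_kind="HA",
    )


def _read_labels(path: Path) -> dict[str, str]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"].astype(str), df["module"].astype(str)))


def _corrcoef(matrix: cx.ExpressionMatrix):
    import numpy as np

    cor = np.corrcoef(matrix.values)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)
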