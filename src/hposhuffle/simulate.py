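"""Synthetic fixture generators with planted ground truth.

The generators emulate the statistical premise of phenotype-aware
re-ranking: a minority of "relevant" genes carries both smaller association
p-values and more phenotype annotations matching the disease repository,
while background genes have uniform p-values and sparse annotations.
Expression data are block-correlated (one shared latent factor per module)
with one module's factor shifted between cases and controls.  Every
generator is a pure function of its configuration (including the seed), and
truth bookkeeping is always returned alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .coexpression import ExpressionMatrix
from .ingest import GeneAssociation, GeneModel, SnpRecord
from .ontology import GenePhenotypeMap, PhenotypeRepository


@dataclass(frozen=True)
class PModel:
    """Association p-value mixture: relevant genes draw from Beta(a, b)
    (defaults give mean 0.1), background from Uniform(0, 1].  Setting
    a = b = 1 makes both components uniform (the null model)."""

    relevant_a: float = 1.0
    relevant_b: float = 9.0


@dataclass
class FixtureConfig:
    # gene universe and annotation structure
    n_genes: int = 2000
    n_relevant: int = 100
    annotation_rate_relevant: float = 3.0
    annotation_rate_background: float = 0.2
    p_model: PModel = field(default_factory=PModel)
    n_hpr_terms: int = 200
    n_background_terms: int = 500
    irrelevant_rate: float = 1.0
    # expression matrix
    n_expr_genes: int = 200
    n_samples: int = 40
    n_modules: int = 4
    within_module_cor: float = 0.8
    trait_effect: float = 1.0
    # SNP panel
    n_snps: int = 1000
    n_geno_samples: int = 200
    frac_low_maf: float = 0.1
    frac_hwe_violating: float = 0.05
    hwe_inbreeding: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_relevant > self.n_genes:
            raise ValidationError("n_relevant must be <= n_genes")
        if not (0.0 <= self.within_module_cor < 1.0):
            raise ValidationError("within_module_cor must be in [0, 1)")
        for name in ("annotation_rate_relevant", "annotation_rate_background", "irrelevant_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng([int(config.seed), stream])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _term_pool(start: int, n: int) -> list[str]:
    return [f"HP:{i:07d}" for i in range(start, start + n)]


def gen_annotations(
    config: FixtureConfig,
) -> tuple[GenePhenotypeMap, PhenotypeRepository, set[str]]:
    """Plant gene annotations.

    Relevant genes draw Poisson(annotation_rate_relevant) HPR-matching
    terms, background genes Poisson(annotation_rate_background); every gene
    additionally draws Poisson(irrelevant_rate) terms outside the HPR.  The
    repository contains exactly the relevant term pool.
    """
    rng = _rng(config, 1)
    genes = _gene_names(config.n_genes)
    hpr_pool = _term_pool(1, config.n_hpr_terms)
    bg_pool = _term_pool(config.n_hpr_terms + 1, config.n_background_terms)

    relevant = set(rng.choice(genes, size=config.n_relevant, replace=False).tolist())
    entries: dict[str, frozenset[str]] = {}
    for g in genes:
        rate = (
            config.annotation_rate_relevant
            if g in relevant
            else config.annotation_rate_background
        )
        m = min(int(rng.poisson(rate)), len(hpr_pool))
        terms = set(rng.choice(hpr_pool, size=m, replace=False).tolist()) if m else set()
        extra = min(int(rng.poisson(config.irrelevant_rate)), len(bg_pool))
        if extra:
            terms |= set(rng.choice(bg_pool, size=extra, replace=False).tolist())
        if terms:
            entries[g] = frozenset(terms)
    gene_map = GenePhenotypeMap(entries=entries)
    hpr = PhenotypeRepository(
        term_ids=frozenset(hpr_pool),
        source_disease_ids=frozenset({"SYN:0000001"}),
        closure_applied=False,
    )
    return gene_map, hpr, relevant


def gen_association_list(
    config: FixtureConfig, truth: set[str], source: str = "GWAS"
) -> list[GeneAssociation]:
    """Draw per-gene association p-values from the two-component mixture."""
    rng = _rng(config, 2 if source == "GWAS" else 3)
    genes = _gene_names(config.n_genes)
    pm = config.p_model
    out = []
    for g in genes:
        if g in truth:
            p = float(rng.beta(pm.relevant_a, pm.relevant_b))
        else:
            p = float(rng.uniform())
        p = min(max(p, 1e-12), 1.0)  # keep inside (0, 1]
        out.append(GeneAssociation(g, p, source))
    return out


def gen_expression(
    config: FixtureConfig,
) -> tuple[ExpressionMatrix, dict[str, str], set[str], set[str]]:
    """Block-correlated expression with one trait-associated module.

    Each of ``n_modules`` modules shares a latent factor; genes load on it
    with sqrt(within_module_cor) so the within-module correlation is
    ``within_module_cor`` in expectation.  The first module's factor is
    shifted by ``trait_effect`` in cases, and half its genes carry a
    negative loading, giving planted up/down directional truth.

    Returns (matrix, planted labels, planted up set, planted down set).
    """
    rng = _rng(config, 4)
    n_g, n_s, n_m = config.n_expr_genes, config.n_samples, config.n_modules
    genes = _gene_names(n_g)
    samples = [f"S{i:03d}" for i in range(1, n_s + 1)]
    trait = np.zeros(n_s, dtype=int)
    trait[: n_s // 2] = 1

    loading = np.sqrt(config.within_module_cor)
    noise_sd = np.sqrt(1.0 - config.within_module_cor)
    block = n_g // n_m
    labels: dict[str, str] = {}
    values = np.empty((n_g, n_s))
    up, down = set(), set()
    for m in range(n_m):
        factor = rng.normal(size=n_s)
        if m == 0:
            factor = factor + config.trait_effect * trait
        lo, hi = m * block, (m + 1) * block if m < n_m - 1 else n_g
        for j, i in enumerate(range(lo, hi)):
            sign = 1.0
            if m == 0 and j % 2 == 1:
                sign = -1.0
            values[i] = sign * loading * factor + noise_sd * rng.normal(size=n_s)
            labels[genes[i]] = f"planted{m + 1}"
            if m == 0:
                (up if sign > 0 else down).add(genes[i])
    matrix = ExpressionMatrix(genes=genes, samples=samples, values=values, trait=trait)
    return matrix, labels, up, down


def gen_snp_panel(
    config: FixtureConfig,
) -> tuple[list[SnpRecord], list[GeneModel], dict]:
    """SNP genotype panel with planted quality-filter violations.

    Normal SNPs draw genotype counts under Hardy-Weinberg proportions at a
    true MAF in (0.1, 0.5); a planted fraction has true MAF in (0.005, 0.04)
    and another planted fraction is sampled with inbreeding-style excess
    homozygosity, which violates equilibrium.  Genes tile a single synthetic
    chromosome; SNP positions are uniform over it.
    """
    rng = _rng(config, 5)
    n = config.n_snps
    n_low = int(round(config.frac_low_maf * n))
    n_hwe = int(round(config.frac_hwe_violating * n))
    kinds = np.array(["low_maf"] * n_low + ["hwe"] * n_hwe + ["ok"] * (n - n_low - n_hwe))
    rng.shuffle(kinds)

    genes = [
        GeneModel(gene=f"G{i:05d}", chrom="1", start=i * 10_000 + 1, end=i * 10_000 + 5_000)
        for i in range(1, max(2, n // 20))
    ]
    span = (len(genes) + 1) * 10_000
    records: list[SnpRecord] = []
    truth = {"low_maf": [], "hwe": [], "ok": []}
    for i, kind in enumerate(kinds, start=1):
        if kind == "low_maf":
            q = rng.uniform(0.005, 0.04)
            f_inb = 0.0
        elif kind == "hwe":
            q = rng.uniform(0.1, 0.5)
            f_inb = config.hwe_inbreeding
        else:
            q = rng.uniform(0.1, 0.5)
            f_inb = 0.0
        p = 1.0 - q
        probs = np.array(
            [p * p + f_inb * p * q, 2 * p * q * (1 - f_inb), q * q + f_inb * p * q]
        )
        counts = rng.multinomial(config.n_geno_samples, probs)
        rec = SnpRecord(
            snp_id=f"rs{i:06d}",
            chrom="1",
            pos=int(rng.integers(1, span)),
            genotype_counts=tuple(int(c) for c in counts),
            assoc_p=float(min(max(rng.uniform(), 1e-12), 1.0)),
        )
        records.append(rec)
        truth[kind].append(rec.snp_id)
    return records, genes, truth


# --- file emission -----------------------------------------------------------


def write_fixture_inputs(config: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise every pipeline input format plus a truth JSON.

    Writes gene/disease annotation TSVs, an HPR term list, GWAS and GEP
    gene-list TSVs, the SNP panel and gene models, the expression matrix and
    trait table, and ``truth.json`` recording all planted structure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gene_map, hpr, relevant = gen_annotations(config)
    rows = [(g, t) for g, ts in sorted(gene_map.entries.items()) for t in sorted(ts)]
    paths["gene_annotations"] = outdir / "gene_annotations.tsv"
    pd.DataFrame(rows, columns=["gene_symbol", "hpo_id"]).to_csv(
        paths["gene_annotations"], sep="\t", index=False
    )
    paths["disease_annotations"] = outdir / "disease_annotations.tsv"
    pd.DataFrame(
        [("SYN:0000001", "SYNTHETIC DISEASE FAMILY", t) for t in sorted(hpr.term_ids)],
        columns=["database_id", "disease_name", "hpo_id"],
    ).to_csv(paths["disease_annotations"], sep="\t", index=False)
    paths["hpr"] = outdir / "hpr.txt"
    paths["hpr"].write_text("".join(f"{t}\n" for t in sorted(hpr.term_ids)))

    for source, fname in (("GWAS", "gwas_genes.tsv"), ("GEP", "gep_genes.tsv")):
        assoc = gen_association_list(config, relevant, source=source)
        paths[fname[:-4]] = outdir / fname
        pd.DataFrame(
            [(a.gene, a.p_value) for a in assoc], columns=["gene", "p"]
        ).to_csv(paths[fname[:-4]], sep="\t", index=False)

    snps, models, snp_truth = gen_snp_panel(config)
    paths["snps"] = outdir / "snps.tsv"
    pd.DataFrame(
        [
            (s.snp_id, s.chrom, s.pos, *s.genotype_counts, s.assoc_p)
            for s in snps
        ],
        columns=["snp", "chrom", "pos", "n_AA", "n_Aa", "n_aa", "p"],
    ).to_csv(paths["snps"], sep="\t", index=False)
    paths["gene_models"] = outdir / "gene_models.tsv"
    pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene) for g in models],
        columns=["chrom", "start", "end", "gene"],
    ).to_csv(paths["gene_models"], sep="\t", index=False)

    matrix, labels, up, down = gen_expression(config)
    paths["expression"] = outdir / "expression.tsv"
    pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples).to_csv(
        paths["expression"], sep="\t", index_label="gene"
    )
    paths["trait"] = outdir / "trait.tsv"
    pd.DataFrame(
        {"sample": matrix.samples, "trait": matrix.trait}
    ).to_csv(paths["trait"], sep="\t", index=False)

    paths["known_genes"] = outdir / "known_genes.txt"
    paths["known_genes"].write_text("".join(f"{g}\n" for g in sorted(relevant)))

    truth = {
        "relevant_genes": sorted(relevant),
        "planted_modules": labels,
        "planted_up": sorted(up),
        "planted_down": sorted(down),
        "snp_truth": snp_truth,
        "config": {**asdict(config), "p_model": asdict(config.p_model)},
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
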