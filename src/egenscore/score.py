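"""Clumped polygenic models of expression with panel-centered scoring.

A model's score for sample s is

    score(s) = sum_i (beta_i * dosage_i(s) - adjustment_i) * called_i(s)

where adjustment_i = beta_i * (P1_i + 2 * P2_i) and P1_i, P2_i are the
fractions of reference-panel individuals carrying exactly one and exactly
two copies of the effect allele. The adjustment centers each SNP's
expected contribution at zero in the panel population, so a missing
genotype (called_i = 0, contribution 0) contributes exactly its
panel-expected value — instead of silently acting as an effect-allele-free
homozygote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np

from .cis import run_cis_scan
from .datatypes import (
    EqtlModel,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    ModelWeight,
    PipelineConfig,
    SNPRecord,
)
from .ld import ReferencePanel, clump

logger = logging.getLogger(__name__)


class AbsentFromPanelError(KeyError):
    """SNP not present in the reference panel."""


@dataclass(frozen=True)
class PanelProportions:
    """Fractions of called panel individuals with exactly 1 and exactly 2
    copies of a SNP's effect allele."""

    snp_id: str
    prop_one: float
    prop_two: float

    def __post_init__(self) -> None:
        if not (0 <= self.prop_one <= 1 and 0 <= self.prop_two <= 1):
            raise ValueError("proportions must lie in [0, 1]")
        if self.prop_one + self.prop_two > 1 + 1e-12:
            raise ValueError("prop_one + prop_two must not exceed 1")


@dataclass
class ScoreVector:
    """Predicted expression (arbitrary units), one value per sample."""

    sample_ids: List[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("score length does not match sample ids")
        if not np.isfinite(self.score).all():
            raise ValueError("scores must be finite")


def genotype_proportions(panel: ReferencePanel, snp: SNPRecord) -> PanelProportions:
    """Empirical heterozygote/homozygote fractions of a SNP in the panel,
    over called panel samples only."""
    d = panel.dosages_for(snp)
    if d is None:
        raise AbsentFromPanelError(f"absent_from_panel: {snp.snp_id}")
    called = d[~np.isnan(d)]
    if called.size == 0:
        raise AbsentFromPanelError(f"absent_from_panel: {snp.snp_id} has no calls")
    return PanelProportions(
        snp_id=snp.snp_id,
        prop_one=float(np.mean(called == 1.0)),
        prop_two=float(np.mean(called == 2.0)),
    )


def adjustment_factor(beta: float, props: PanelProportions) -> float:
    """beta times the expected effect-allele dosage in the panel."""
    return beta * props.prop_one + 2.0 * beta * props.prop_two


def build_egenscore_model(
    gene: GeneRecord,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: ReferencePanel,
    config: PipelineConfig,
    training_label: str = "",
) -> EqtlModel:
    """Train one gene's clumped polygenic model.

    Pipeline: per-SNP cis regression -> keep nominal p below the
    association threshold -> drop SNPs absent from or monomorphic in the
    panel -> greedy LD clumping -> panel-based adjustment factor per
    surviving SNP. Genes where no SNP survives yield a valid null model.
    """
    assoc = run_cis_scan(gene, genotypes, expression, config)
    nominal = [a for a in assoc if a.p < config.assoc_p_threshold]
    usable = []
    for a in nominal:
        d = panel.dosages_for(a.snp)
        if d is None:
            logger.warning("%s: %s absent from panel, dropped", gene.gene_id, a.snp.snp_id)
            continue
        called = d[~np.isnan(d)]
        if called.size < 3 or np.ptp(called) == 0:
            logger.warning(
                "%s: %s monomorphic in panel, dropped", gene.gene_id, a.snp.snp_id
            )
            continue
        usable.append(a)
    retained = clump(usable, panel, config.clump_r2_threshold)
    weights: List[ModelWeight] = []
    for a in retained:
        props = genotype_proportions(panel, a.snp)
        weights.append(
            ModelWeight(
                snp=a.snp,
                beta=a.beta,
                adjustment=adjustment_factor(a.beta, props),
            )
        )
    return EqtlModel(
        gene_id=gene.gene_id,
        framework="egenscore",
        weights=weights,
        metadata={
            "seed": config.seed,
            "training_label": training_label,
            "panel": panel.label,
        },
    )


def score_egenscore(model: EqtlModel, genotypes: GenotypeMatrix) -> ScoreVector:
    """Score a cohort with a clumped polygenic model.

    Per sample, each model SNP contributes beta * dosage - adjustment
    where its genotype is called and exactly 0 where it is missing;
    model SNPs absent from the cohort contribute 0 for every sample
    (treated as uncalled). Genotypes must already be harmonized to the
    model's effect alleles.
    """
    if model.framework != "egenscore":
        raise ValueError(f"expected an egenscore model, got {model.framework!r}")
    total = np.zeros(genotypes.n_samples, dtype=float)
    for w in model.weights:
        j = genotypes.locus_column(w.snp.chrom, w.snp.pos)
        if j is None:
            logger.warning(
                "scoring %s: %s absent from cohort, contributes 0",
                model.gene_id,
                w.snp.snp_id,
            )
            continue
        d = genotypes.dosage[:, j]
        called = ~np.isnan(d)
        contrib = np.where(called, w.beta * np.nan_to_num(d) - w.adjustment, 0.0)
        total += contrib
    return ScoreVector(sample_ids=list(genotypes.sample_ids), score=total)
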