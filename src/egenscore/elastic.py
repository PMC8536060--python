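"""Elastic-net expression models on cis SNPs, in the PrediXcan tradition.

All cis SNPs of a gene enter one penalized regression that performs
variable selection (L1) and correlated-predictor shrinkage (L2) jointly,
with mixing parameter alpha = 0.5 between the two penalties and the
penalty weight chosen by internal 10-fold cross-validation minimizing
mean squared error over a log-spaced path. Missing dosages are
mean-imputed per SNP for fitting; at scoring time they are replaced by
zero — i.e. a missing genotype is treated as an effect-allele-free
homozygote, with no population centering. The contrast between that
convention and the panel-centered treatment in :mod:`egenscore.score`
is the methodological comparison this package exists to make.
"""

from __future__ import annotations

import logging
from typing import List

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .cis import select_cis_snps
from .datatypes import (
    EqtlModel,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    ModelWeight,
    PipelineConfig,
)
from .score import ScoreVector

logger = logging.getLogger(__name__)


class NoCisSNPsError(ValueError):
    """No cis SNP available for the gene."""


def _mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace nan entries with the per-SNP mean of called dosages."""
    X = dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X


def train_elastic_net(
    gene: GeneRecord,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    config: PipelineConfig,
    training_label: str = "",
) -> EqtlModel:
    """Fit one gene's elastic-net model on its cis SNPs.

    SNPs with zero variance after mean imputation are excluded from the
    design; if none remain the result is a valid null model. The mixing
    parameter comes from ``config.alpha`` (default 0.5) and the penalty
    path CV is seeded from ``config.seed`` for reproducibility.

    Raises
    ------
    NoCisSNPsError
        if the gene has no cis SNP at all.
    """
    if gene.gene_id not in expression:
        raise KeyError(f"unknown_gene: {gene.gene_id}")
    if genotypes.sample_ids != expression.sample_ids:
        raise ValueError("genotype and expression sample orders differ; align first")
    cis = select_cis_snps(gene, genotypes, config.cis_window_bp)
    if not cis:
        raise NoCisSNPsError(f"no_cis_snps: {gene.gene_id}")
    cols = [genotypes.locus_column(s.chrom, s.pos) for s in cis]
    X = _mean_impute(genotypes.dosage[:, cols])
    variable = np.ptp(X, axis=0) > 0
    metadata = {
        "alpha": config.alpha,
        "seed": config.seed,
        "training_label": training_label,
    }
    if not variable.any():
        logger.warning("%s: all cis SNPs constant, null model", gene.gene_id)
        return EqtlModel(gene.gene_id, "elasticnet", [], metadata)
    X = X[:, variable]
    snps = [s for s, v in zip(cis, variable) if v]
    y = expression.gene_values(gene.gene_id)
    n_splits = min(10, X.shape[0])
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=config.seed % (2**31))
    fit = ElasticNetCV(
        l1_ratio=config.alpha,
        alphas=100,  # 100-point log-spaced penalty path
        cv=cv,
        max_iter=5000,
        tol=1e-5,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fit.fit(X, y)
    weights: List[ModelWeight] = [
        ModelWeight(snp=snp, beta=float(coef), adjustment=0.0)
        for snp, coef in zip(snps, fit.coef_)
        if coef != 0.0
    ]
    metadata["penalty"] = float(fit.alpha_)
    return EqtlModel(gene.gene_id, "elasticnet", weights, metadata)


def score_elasticnet(model: EqtlModel, genotypes: GenotypeMatrix) -> ScoreVector:
    """Score a cohort with an elastic-net model.

    Per sample the score is the plain weighted dosage sum; a missing
    dosage contributes 0 (zero-substitution, no centering term), and
    model SNPs absent from the cohort contribute 0 for every sample.
    Genotypes must be harmonized to the model's effect alleles.
    """
    if model.framework != "elasticnet":
        raise ValueError(f"expected an elasticnet model, got {model.framework!r}")
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
        total += w.beta * np.nan_to_num(genotypes.dosage[:, j])
    return ScoreVector(sample_ids=list(genotypes.sample_ids), score=total)
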