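"""Cis-SNP selection and single-SNP expression regressions.

Each candidate SNP within the cis window (gene body +/- window, both ends
inclusive) is regressed individually against the gene's expression under
additive allele coding (dosage 0/1/2), with an intercept. Samples whose
genotype is missing at a SNP are excluded pairwise from that SNP's fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    PipelineConfig,
    SNPRecord,
)

logger = logging.getLogger(__name__)


class MonomorphicSNPError(ValueError):
    """Dosage constant among called samples: no association is estimable."""


class InsufficientSamplesError(ValueError):
    """Fewer than 3 called samples."""


class UnknownGeneError(KeyError):
    """Gene absent from the expression matrix."""


@dataclass(frozen=True)
class AssocResult:
    """OLS fit of expression on one SNP's dosage: beta is expression units
    per effect allele; p is the two-sided test of beta = 0 on n_used - 2 df."""

    snp: SNPRecord
    beta: float
    se: float
    t_stat: float
    p: float
    n_used: int


def select_cis_snps(
    gene: GeneRecord, genotypes: GenotypeMatrix, window_bp: int
) -> List[SNPRecord]:
    """SNPs on the gene's chromosome within window_bp of the gene body.

    The window is closed: positions gene.start - window_bp and
    gene.end + window_bp are both included. Input order is preserved.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    lo = gene.start - window_bp
    hi = gene.end + window_bp
    return [
        snp
        for snp in genotypes.snps
        if snp.chrom == gene.chrom and lo <= snp.pos <= hi
    ]


def fit_single_snp(dosage: np.ndarray, expression: np.ndarray) -> AssocResult | None:
    """Least-squares regression of expression on one SNP's dosage.

    ``dosage`` may contain nan (uncalled genotypes); those samples are
    dropped for this SNP only. Returns beta, its standard error, the t
    statistic and the two-sided p-value from the t distribution with
    n_used - 2 degrees of freedom. A perfect fit yields p = 0.

    Raises
    ------
    InsufficientSamplesError
        if fewer than 3 samples are called.
    MonomorphicSNPError
        if the dosage is constant among called samples.
    """
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    mask = ~np.isnan(dosage)
    g = dosage[mask]
    y = expression[mask]
    n = g.size
    if n < 3:
        raise InsufficientSamplesError(f"insufficient_n: {n} called samples")
    if np.ptp(g) == 0:
        raise MonomorphicSNPError("monomorphic: constant dosage among called samples")
    fit = stats.linregress(g, y)
    se = float(fit.stderr)
    beta = float(fit.slope)
    t_stat = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(min(max(fit.pvalue, 0.0), 1.0))
    return AssocResult(snp=None, beta=beta, se=se, t_stat=float(t_stat), p=p, n_used=n)


def run_cis_scan(
    gene: GeneRecord,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    config: PipelineConfig,
) -> List[AssocResult]:
    """Fit every cis SNP of a gene individually against its expression.

    Genotype and expression sample orders must already be aligned
    (see :func:`egenscore.datatypes.align_samples`). Monomorphic SNPs
    and SNPs with fewer than 3 called samples are skipped with a log
    message. Results are sorted by (chrom, pos, snp_id).
    """
    if gene.gene_id not in expression:
        raise UnknownGeneError(f"unknown_gene: {gene.gene_id}")
    if genotypes.sample_ids != expression.sample_ids:
        raise ValueError("genotype and expression sample orders differ; align first")
    y = expression.gene_values(gene.gene_id)
    results: List[AssocResult] = []
    for snp in select_cis_snps(gene, genotypes, config.cis_window_bp):
        j = genotypes.locus_column(snp.chrom, snp.pos)
        try:
            fit = fit_single_snp(genotypes.dosage[:, j], y)
        except (MonomorphicSNPError, InsufficientSamplesError) as exc:
            logger.debug("cis scan %s: skipping %s (%s)", gene.gene_id, snp.snp_id, exc)
            continue
        results.append(
            AssocResult(
                snp=snp,
                beta=fit.beta,
                se=fit.se,
                t_stat=fit.t_stat,
                p=fit.p,
                n_used=fit.n_used,
            )
        )
    results.sort(key=lambda r: (r.snp.chrom, r.snp.pos, r.snp.snp_id))
    return results
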