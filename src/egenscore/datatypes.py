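"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as effect-allele dosages (0, 1, 2) in a dense float
matrix with ``nan`` marking uncalled genotypes; the boolean ``called`` mask
derived from it drives the missing-genotype contract of the scoring rules.
Expression arrives pre-normalized and covariate-corrected; no normalization
is performed anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

#: Autosome labels accepted throughout; sex chromosomes are always dropped.
AUTOSOMES = frozenset(str(c) for c in range(1, 23))

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic autosomal SNP with a designated effect allele.

    All model weights (betas) in this package refer to the count of
    ``effect_allele``; ``other_allele`` is kept for allele harmonization
    between cohorts genotyped on opposite strands or orientations.
    """

    snp_id: str
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")

    @property
    def key(self) -> Tuple[str, int]:
        """(chrom, pos) locus key used for cross-cohort matching."""
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be disambiguated across strands."""
        return self.alleles in (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval; strand is bookkeeping only (cis windows are symmetric)."""

    gene_id: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


class GenotypeMatrix:
    """Samples x SNPs effect-allele dosage matrix with explicit missingness.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    snps
        One :class:`SNPRecord` per column.
    dosage
        Float matrix of shape ``(len(sample_ids), len(snps))`` holding
        0/1/2 effect-allele counts, with ``nan`` where the genotype is
        not called.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        snps: Sequence[SNPRecord],
        dosage: np.ndarray,
    ) -> None:
        self.sample_ids: List[str] = list(sample_ids)
        self.snps: List[SNPRecord] = list(snps)
        self.dosage = np.asarray(dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        called_values = self.dosage[~np.isnan(self.dosage)]
        if called_values.size and not np.isin(called_values, (0.0, 1.0, 2.0)).all():
            raise ValueError("called dosages must be 0, 1 or 2")
        self._locus_index: Dict[Tuple[str, int], int] = {
            snp.key: j for j, snp in enumerate(self.snps)
        }

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask, True where the genotype is present."""
        return ~np.isnan(self.dosage)

    def locus_column(self, chrom: str, pos: int) -> int | None:
        """Column index of the SNP at (chrom, pos), or None if absent."""
        return self._locus_index.get((chrom, pos))

    # -- subsetting ----------------------------------------------------------

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index], self.snps, self.dosage[index, :]
        )

    def subset_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.sample_ids, [self.snps[j] for j in index], self.dosage[:, index]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


class ExpressionMatrix:
    """Genes x samples matrix of pre-normalized expression values."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        self.gene_ids: List[str] = list(gene_ids)
        self.sample_ids: List[str] = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix must not contain missing values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def gene_values(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene, in this matrix's sample order."""
        try:
            return self.values[self._gene_index[gene_id], :]
        except KeyError:
            raise KeyError(f"unknown_gene: {gene_id!r} not in expression matrix")

    def subset_samples(self, index: Sequence[int]) -> "ExpressionMatrix":
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            self.gene_ids, [self.sample_ids[i] for i in index], self.values[:, index]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples)"
        )


@dataclass(frozen=True)
class ModelWeight:
    """One SNP term of a trained model: beta per effect allele, plus the
    population-expected contribution subtracted at scoring time (0 for
    elastic-net models, which carry no centering)."""

    snp: SNPRecord
    beta: float
    adjustment: float = 0.0


@dataclass
class EqtlModel:
    """A trained per-gene expression model: the unit that is serialized,
    validated, and scored.

    ``framework`` is either ``"egenscore"`` (clumped single-SNP weights with
    panel adjustments) or ``"elasticnet"`` (penalized multi-SNP weights,
    adjustment identically 0). An empty ``weights`` list is a valid null
    model that predicts 0 for every sample.
    """

    gene_id: str
    framework: str
    weights: List[ModelWeight] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.framework not in ("egenscore", "elasticnet"):
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.framework == "elasticnet":
            for w in self.weights:
                if w.adjustment != 0.0:
                    raise ValueError(
                        "elasticnet models must have zero adjustment factors"
                    )

    @property
    def is_null(self) -> bool:
        return not self.weights


@dataclass
class PipelineConfig:
    """Tunable thresholds of the whole pipeline, with the published defaults.

    cis_window_bp
        Half-width of the cis window around the gene body (both ends
        inclusive); candidate SNPs must lie within this distance of the
        gene's start or end.
    assoc_p_threshold
        Nominal single-SNP association p-value below which a SNP enters
        the clumping stage.
    clump_r2_threshold
        Pairwise LD ceiling: of any pair with panel r-squared above this,
        the less significant SNP is removed.
    n_folds
        Folds of the internal cross-validation.
    sig_r_threshold / sig_p_threshold
        A model is internally significant when the fold-averaged Pearson
        correlation exceeds sig_r_threshold in absolute value AND the
        Fisher-combined p-value is below sig_p_threshold.
    alpha
        Elastic-net mixing parameter (1 = lasso, 0 = ridge).
    """

    cis_window_bp: int = 1_000_000
    assoc_p_threshold: float = 0.05
    clump_r2_threshold: float = 0.3
    n_folds: int = 5
    sig_r_threshold: float = 0.1
    sig_p_threshold: float = 0.05
    alpha: float = 0.5
    seed: int = 0
    drop_strand_ambiguous: bool = False

    def __post_init__(self) -> None:
        for name in (
            "cis_window_bp",
            "assoc_p_threshold",
            "clump_r2_threshold",
            "sig_r_threshold",
            "sig_p_threshold",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def align_samples(
    genotypes: GenotypeMatrix, expression: ExpressionMatrix
) -> Tuple[GenotypeMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared samples, in genotype order.

    Raises ``ValueError`` if the overlap is empty.
    """
    expr_pos = {s: i for i, s in enumerate(expression.sample_ids)}
    geno_keep = [i for i, s in enumerate(genotypes.sample_ids) if s in expr_pos]
    if not geno_keep:
        raise ValueError("genotype and expression matrices share no samples")
    geno = genotypes.subset_samples(geno_keep)
    expr = expression.subset_samples([expr_pos[s] for s in geno.sample_ids])
    return geno, expr
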