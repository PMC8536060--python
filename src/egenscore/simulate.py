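"""Synthetic genotype-expression cohorts with controlled LD, causal
architecture, heritability and missingness.

The real training resources this package targets (brain expression
cohorts of ~130-160 donors, an external validation cohort of ~210, and a
~500-individual sequencing reference panel) are access-restricted, so
this module generates structurally matched stand-ins from one generative
model:

* genotypes follow a threshold-Gaussian model — per haplotype, a latent
  multivariate normal with block-diagonal equicorrelation (constant rho
  within blocks, zero between) is thresholded at each SNP's minor-allele
  frequency quantile, and two independent haplotype draws are summed to a
  dosage in {0, 1, 2}. Within-block rho directly controls the dosage
  r-squared that the clumping stage sees;
* expression is a sparse causal model: n_causal SNPs per gene receive
  standard-normal effects, and Gaussian noise is scaled so that the
  genetic fraction of expression variance matches the target
  heritability h2 in each cohort;
* a training cohort, a reference panel (no missingness) and an external
  cohort are drawn independently from the same MAFs, LD blocks and
  causal effects, with disjoint sample-id namespaces.

Default cohort sizes mirror the real study design (150 training, 503
panel, 214 external individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, GeneRecord, GenotypeMatrix, SNPRecord
from .ld import ReferencePanel

_GENE_SPACING_BP = 10_000_000  # keeps +/-1 Mb cis windows of distinct genes disjoint
_GENE_LENGTH_BP = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generative model. Defaults emulate the real study:
    a ~150-donor training cohort, a 503-individual reference panel, a
    214-donor external cohort, 100 cis SNPs per gene in LD blocks of 10,
    one causal SNP, heritability 0.5, 2% missing genotypes (panel: 0%)."""

    n_train: int = 150
    n_panel: int = 503
    n_external: int = 214
    n_genes: int = 20
    snps_per_gene: int = 100
    block_size: int = 10
    within_block_rho: float = 0.8
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_causal: int = 1
    h2: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must lie in [0, 1)")
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_causal > self.snps_per_gene:
            raise ValueError("n_causal cannot exceed snps_per_gene")
        if min(self.n_train, self.n_panel, self.n_external) < 2:
            raise ValueError("all cohort sizes must be >= 2")
        if self.block_size < 1 or self.snps_per_gene < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene, recorded before noise."""

    gene_id: str
    causal_snp_ids: List[str]
    effects: np.ndarray  # per causal SNP, expression units per effect allele
    realized_h2: float = float("nan")


@dataclass
class SimTruth:
    genes: Dict[str, GeneTruth] = field(default_factory=dict)


@dataclass
class SimStudy:
    """A full synthetic study: training cohort, matched reference panel,
    independent external cohort, gene annotation, and ground truth."""

    genes: List[GeneRecord]
    train_genotypes: GenotypeMatrix
    train_expression: ExpressionMatrix
    panel: ReferencePanel
    external_genotypes: GenotypeMatrix
    external_expression: ExpressionMatrix
    truth: SimTruth


# ---------------------------------------------------------------------------
# Shared genetic architecture
# ---------------------------------------------------------------------------

@dataclass
class _Architecture:
    """SNP map, MAFs and causal effects shared by all cohorts of a study."""

    genes: List[GeneRecord]
    snps: List[SNPRecord]
    mafs: np.ndarray  # per SNP
    gene_slices: List[slice]  # columns of each gene's SNPs
    causal_idx: List[np.ndarray]  # per gene, column indices into snps
    effects: List[np.ndarray]  # per gene, effect sizes


def _draw_architecture(config: SimConfig, rng: np.random.Generator) -> _Architecture:
    bases = np.array(list("ACGT"))
    genes: List[GeneRecord] = []
    snps: List[SNPRecord] = []
    gene_slices: List[slice] = []
    causal_idx: List[np.ndarray] = []
    effects: List[np.ndarray] = []
    mafs = rng.uniform(*config.maf_range, size=config.n_genes * config.snps_per_gene)
    for g in range(config.n_genes):
        chrom = str((g % 22) + 1)
        start = 50_000_000 + (g // 22) * _GENE_SPACING_BP
        end = start + _GENE_LENGTH_BP
        gene_id = f"GENE{g + 1:04d}"
        genes.append(GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end))
        lo = start - 500_000
        hi = end + 500_000
        positions = np.sort(
            rng.choice(np.arange(lo, hi), size=config.snps_per_gene, replace=False)
        )
        first = len(snps)
        for k, pos in enumerate(positions):
            ref, alt = rng.choice(bases, size=2, replace=False)
            snps.append(
                SNPRecord(
                    snp_id=f"{gene_id}_snp{k + 1:04d}",
                    chrom=chrom,
                    pos=int(pos),
                    effect_allele=str(alt),
                    other_allele=str(ref),
                )
            )
        gene_slices.append(slice(first, first + config.snps_per_gene))
        causal = rng.choice(config.snps_per_gene, size=config.n_causal, replace=False)
        causal_idx.append(first + np.sort(causal))
        effects.append(rng.standard_normal(config.n_causal))
    return _Architecture(genes, snps, mafs, gene_slices, causal_idx, effects)


def _draw_dosages(
    n: int,
    mafs: np.ndarray,
    block_size: int,
    rho: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold-Gaussian dosages: two haplotype draws per individual,
    equicorrelated latents within blocks, thresholded at the MAF quantile."""
    n_snps = mafs.size
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n, n_snps), dtype=float)
    for _ in range(2):  # two haplotypes
        latent = np.empty((n, n_snps))
        for start in range(0, n_snps, block_size):
            stop = min(start + block_size, n_snps)
            m = stop - start
            shared = rng.standard_normal((n, 1))
            indiv = rng.standard_normal((n, m))
            latent[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * indiv
        dosage += (latent < thresholds).astype(float)
    if missing_rate > 0:
        dosage[rng.random((n, n_snps)) < missing_rate] = np.nan
    return dosage


def _genetic_values(
    dosage: np.ndarray, causal_cols: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Weighted causal dosage sum; missing entries are mean-imputed for
    simulation only (observed expression has no holes)."""
    X = dosage[:, causal_cols].copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X @ betas


def _expression_from(
    arch: _Architecture,
    dosage: np.ndarray,
    sample_ids: List[str],
    h2: float,
    rng: np.random.Generator,
    truth: SimTruth | None = None,
) -> ExpressionMatrix:
    values = np.empty((len(arch.genes), len(sample_ids)))
    for i, gene in enumerate(arch.genes):
        g = _genetic_values(dosage, arch.causal_idx[i], arch.effects[i])
        var_g = float(np.var(g))
        if h2 == 0 or var_g == 0:
            y = rng.standard_normal(len(sample_ids))
        elif h2 == 1:
            y = g
        else:
            sd_e = np.sqrt(var_g * (1 - h2) / h2)
            y = g + rng.normal(0.0, sd_e, size=len(sample_ids))
        values[i] = y
        if truth is not None:
            var_y = float(np.var(y))
            realized = 0.0 if h2 == 0 or var_y == 0 else var_g / var_y
            truth.genes[gene.gene_id] = GeneTruth(
                gene_id=gene.gene_id,
                causal_snp_ids=[arch.snps[c].snp_id for c in arch.causal_idx[i]],
                effects=arch.effects[i].copy(),
                realized_h2=realized,
            )
    return ExpressionMatrix([g.gene_id for g in arch.genes], sample_ids, values)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def simulate_genotypes(n: int, config: SimConfig, prefix: str = "S") -> GenotypeMatrix:
    """One cohort of n individuals from a freshly drawn architecture.

    Deterministic given ``config.seed``; for cohorts sharing one
    architecture use :func:`simulate_study`.
    """
    rng = np.random.default_rng(config.seed)
    arch = _draw_architecture(config, rng)
    dosage = _draw_dosages(
        n, arch.mafs, config.block_size, config.within_block_rho,
        config.missing_rate, rng,
    )
    ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(ids, arch.snps, dosage)


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig
) -> Tuple[ExpressionMatrix, SimTruth]:
    """Sparse-causal expression for an existing cohort.

    The architecture (causal SNP choice and effects) is re-derived from
    ``config.seed``; SNP columns are assumed grouped per gene in blocks
    of ``snps_per_gene`` as produced by :func:`simulate_genotypes`.
    """
    if genotypes.n_snps != config.n_genes * config.snps_per_gene:
        raise ValueError(
            "genotype matrix shape does not match config gene/SNP layout"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    arch = _draw_architecture(config, np.random.default_rng(config.seed))
    # keep the cohort's actual SNP records (positions may differ when the
    # genotypes came from disk) but reuse the seeded causal layout
    arch.snps = genotypes.snps
    truth = SimTruth()
    expr = _expression_from(
        arch, genotypes.dosage, list(genotypes.sample_ids), config.h2, rng, truth
    )
    return expr, truth


def simulate_study(config: SimConfig) -> SimStudy:
    """Training cohort + matched reference panel + external cohort, all
    drawn from one architecture (shared MAFs, LD blocks, causal effects).

    The panel has no missing genotypes; sample-id namespaces are
    disjoint (TRAIN/PANEL/EXT prefixes). Bit-identical given the seed.
    """
    root = np.random.SeedSequence(config.seed)
    s_arch, s_train, s_panel, s_ext, s_ey_train, s_ey_ext = [
        np.random.default_rng(s) for s in root.spawn(6)
    ]
    arch = _draw_architecture(config, s_arch)
    truth = SimTruth()

    d_train = _draw_dosages(
        config.n_train, arch.mafs, config.block_size, config.within_block_rho,
        config.missing_rate, s_train,
    )
    train_ids = [f"TRAIN{i + 1:05d}" for i in range(config.n_train)]
    train_geno = GenotypeMatrix(train_ids, arch.snps, d_train)
    train_expr = _expression_from(
        arch, d_train, train_ids, config.h2, s_ey_train, truth
    )

    d_panel = _draw_dosages(
        config.n_panel, arch.mafs, config.block_size, config.within_block_rho,
        0.0, s_panel,
    )
    panel_ids = [f"PANEL{i + 1:05d}" for i in range(config.n_panel)]
    panel = ReferencePanel(
        genotypes=GenotypeMatrix(panel_ids, arch.snps, d_panel),
        label="synthetic_panel",
    )

    d_ext = _draw_dosages(
        config.n_external, arch.mafs, config.block_size, config.within_block_rho,
        config.missing_rate, s_ext,
    )
    ext_ids = [f"EXT{i + 1:05d}" for i in range(config.n_external)]
    ext_geno = GenotypeMatrix(ext_ids, arch.snps, d_ext)
    ext_expr = _expression_from(arch, d_ext, ext_ids, config.h2, s_ey_ext)

    return SimStudy(
        genes=arch.genes,
        train_genotypes=train_geno,
        train_expression=train_expr,
        panel=panel,
        external_genotypes=ext_geno,
        external_expression=ext_expr,
        truth=truth,
    )


def truth_frame(truth: SimTruth):
    """Ground truth as a flat table (one row per causal SNP)."""
    import pandas as pd

    rows = []
    for gt in truth.genes.values():
        for snp_id, beta in zip(gt.causal_snp_ids, gt.effects):
            rows.append(
                {
                    "gene_id": gt.gene_id,
                    "causal_snp_id": snp_id,
                    "effect": beta,
                    "realized_h2": gt.realized_h2,
                }
            )
    return pd.DataFrame(rows)
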