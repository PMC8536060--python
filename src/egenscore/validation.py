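"""Internal k-fold cross-validation and external-cohort validation.

Internal validation retrains the *entire* pipeline (association scan,
clumping and adjustment — or the elastic net) on each set of k-1 folds
and scores the hold-out fold, so no stage ever sees hold-out expression.
Per fold, the Pearson correlation r between observed expression and the
model's score is recorded with its two-sided p-value; the fold r values
are averaged (r_avg) and their p-values combined by Fisher's method
(-2 * sum(ln p) against chi-square with 2k df). A model is declared
significant when |r_avg| exceeds the correlation threshold AND the
combined p falls below the significance level — both thresholds come
from :class:`~egenscore.datatypes.PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    EqtlModel,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    PipelineConfig,
    align_samples,
)
from .elastic import score_elasticnet, train_elastic_net
from .ld import ReferencePanel
from .score import ScoreVector, build_egenscore_model, score_egenscore

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # clamp before taking logs in Fisher's method

Trainer = Callable[..., EqtlModel]


@dataclass(frozen=True)
class FoldResult:
    fold_index: int  # 1-based
    r: float
    p: float
    n_test: int


@dataclass
class InternalValidationResult:
    gene_id: str
    framework: str
    folds: List[FoldResult]
    r_avg: float
    r_avg_sq: float
    fisher_stat: float
    fisher_df: int
    fisher_p: float
    significant: bool
    training_label: str = ""


@dataclass
class ExternalValidationResult:
    gene_id: str
    framework: str
    r: float
    r_sq: float
    p: float
    significant: bool
    training_label: str = ""


def kfold_split(n_samples: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform random partition into k folds.

    Returns an integer array of length ``n_samples`` with fold labels
    0..k-1; fold sizes differ by at most one. Deterministic given seed.
    """
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignment = np.empty(n_samples, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


def fisher_combine(pvals: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: combine independent p-values.

    Returns (statistic, df, combined_p) with statistic = -2 * sum(ln p)
    and df = 2 * len(pvals); p-values are clamped to [1e-300, 1] before
    the logarithm.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    clamped = np.clip(pvals, P_FLOOR, 1.0)
    stat = float(-2.0 * np.sum(np.log(clamped)))
    df = 2 * pvals.size
    return stat, df, float(stats.chi2.sf(stat, df))


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p under the no-correlation null.

    Degenerate input (either vector constant, or fewer than 3 points)
    yields (0.0, 1.0) so that an uninformative model is penalized rather
    than erroring out.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def score_model(model: EqtlModel, genotypes: GenotypeMatrix) -> ScoreVector:
    """Dispatch to the framework-appropriate scorer."""
    if model.framework == "egenscore":
        return score_egenscore(model, genotypes)
    return score_elasticnet(model, genotypes)


def make_trainer(framework: str) -> Trainer:
    """Uniform trainer signature (gene, genotypes, expression, panel,
    config, training_label) for either framework; the elastic net simply
    ignores the panel."""
    if framework == "egenscore":
        return build_egenscore_model
    if framework == "elasticnet":
        return lambda gene, geno, expr, panel, config, training_label="": (
            train_elastic_net(gene, geno, expr, config, training_label)
        )
    raise ValueError(f"unknown framework {framework!r}")


def internal_validate(
    trainer: Trainer,
    gene: GeneRecord,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: ReferencePanel,
    config: PipelineConfig,
    training_label: str = "",
) -> InternalValidationResult:
    """k-fold cross-validation of one gene's model.

    For every fold the full training pipeline is re-run on the other
    k-1 folds and the hold-out fold is scored; leakage is impossible by
    construction (the panel is an external cohort). Degenerate folds
    (constant score, e.g. from a null model) contribute r = 0, p = 1 and
    are retained, keeping the Fisher df fixed at 2k.
    """
    geno, expr = align_samples(genotypes, expression)
    assignment = kfold_split(geno.n_samples, config.n_folds, config.seed)
    folds: List[FoldResult] = []
    framework = None
    for fold in range(config.n_folds):
        train_idx = np.flatnonzero(assignment != fold)
        test_idx = np.flatnonzero(assignment == fold)
        model = trainer(
            gene,
            geno.subset_samples(train_idx),
            expr.subset_samples(train_idx),
            panel,
            config,
            training_label,
        )
        framework = model.framework
        scores = score_model(model, geno.subset_samples(test_idx))
        observed = expr.subset_samples(test_idx).gene_values(gene.gene_id)
        r, p = correlation_with_p(scores.score, observed)
        folds.append(FoldResult(fold_index=fold + 1, r=r, p=p, n_test=test_idx.size))
    r_avg = float(np.mean([f.r for f in folds]))
    stat, df, fisher_p = fisher_combine([f.p for f in folds])
    significant = bool(
        abs(r_avg) > config.sig_r_threshold and fisher_p < config.sig_p_threshold
    )
    return InternalValidationResult(
        gene_id=gene.gene_id,
        framework=framework,
        folds=folds,
        r_avg=r_avg,
        r_avg_sq=r_avg**2,
        fisher_stat=stat,
        fisher_df=df,
        fisher_p=fisher_p,
        significant=significant,
        training_label=training_label,
    )


def external_validate(
    model: EqtlModel,
    ext_genotypes: GenotypeMatrix,
    ext_expression: ExpressionMatrix,
    sig_p_threshold: float = 0.05,
) -> ExternalValidationResult:
    """Validate a trained model on an independent cohort.

    The external cohort is scored with the model's own framework
    convention; significance is a plain p < threshold test of the
    Pearson correlation between score and observed expression. A
    constant score vector (null model) gives r = 0, p = 1.
    """
    geno, expr = align_samples(ext_genotypes, ext_expression)
    scores = score_model(model, geno)
    observed = expr.gene_values(model.gene_id)
    r, p = correlation_with_p(scores.score, observed)
    if np.ptp(scores.score) == 0:
        logger.info("external validation %s: constant score vector", model.gene_id)
    return ExternalValidationResult(
        gene_id=model.gene_id,
        framework=model.framework,
        r=r,
        r_sq=r**2,
        p=p,
        significant=bool(p < sig_p_threshold),
        training_label=str(model.metadata.get("training_label", "")),
    )


# ---------------------------------------------------------------------------
# Report TSVs
# ---------------------------------------------------------------------------

def internal_report_frame(
    results: Sequence[InternalValidationResult],
) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "gene_id": res.gene_id,
            "framework": res.framework,
            "training_label": res.training_label,
        }
        for f in res.folds:
            row[f"r_fold{f.fold_index}"] = f.r
        row.update(
            r_avg=res.r_avg,
            r_avg_sq=res.r_avg_sq,
            fisher_p=res.fisher_p,
            significant=res.significant,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def external_report_frame(
    results: Sequence[ExternalValidationResult],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": res.gene_id,
                "framework": res.framework,
                "training_label": res.training_label,
                "r": res.r,
                "r_sq": res.r_sq,
                "p": res.p,
                "significant": res.significant,
            }
            for res in results
        ]
    )


def write_report(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
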