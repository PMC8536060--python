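"""Paired performance comparison between frameworks or training cohorts.

Two validation reports over the same gene universe are intersected on
the genes significant in both, and their per-gene explained-variance
metrics (fold-averaged r squared internally, external r squared
externally) are compared with a two-tailed paired t-test. The effect
size is the paired standardized mean difference (Cohen's d_z),

    d = |mean(diff)| / sd(diff) = |t| / sqrt(n),

reported as a non-negative number regardless of the sign of t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateComparisonError(ValueError):
    """All paired differences identical: the t statistic is undefined."""


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    n_genes: int
    df: int  # n_genes - 1
    t_stat: float
    p: float
    cohens_d: float  # non-negative paired d_z

    def as_row(self) -> dict:
        return {
            "comparison": f"{self.label_a} vs {self.label_b}",
            "n_genes": self.n_genes,
            "df": self.df,
            "t": self.t_stat,
            "p": self.p,
            "cohens_d": self.cohens_d,
        }


def select_comparable_genes(
    report_a: pd.DataFrame, report_b: pd.DataFrame
) -> List[str]:
    """Genes whose models are significant in BOTH reports, sorted."""
    sig_a = set(report_a.loc[report_a["significant"].astype(bool), "gene_id"])
    sig_b = set(report_b.loc[report_b["significant"].astype(bool), "gene_id"])
    return sorted(sig_a & sig_b)


def paired_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Two-tailed paired t-test with Cohen's d_z on matched per-gene metrics.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on differences d = a - b with
    n - 1 degrees of freedom (sample sd, n-1 denominator), and
    ``cohens_d = |mean(d)| / sd(d)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length_mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison requires at least 2 genes")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateComparisonError("degenerate: all paired differences equal")
    res = stats.ttest_rel(a, b)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_genes=n,
        df=n - 1,
        t_stat=float(res.statistic),
        p=float(res.pvalue),
        cohens_d=float(abs(diff.mean()) / sd),
    )


def compare_reports(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    metric: str,
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Intersect two reports on shared significant genes and run the
    paired test on the named metric column (``r_avg_sq`` or ``r_sq``)."""
    genes = select_comparable_genes(report_a, report_b)
    if not genes:
        raise ValueError("no gene is significant in both reports")
    a = report_a.set_index("gene_id").loc[genes, metric].to_numpy(float)
    b = report_b.set_index("gene_id").loc[genes, metric].to_numpy(float)
    return paired_compare(a, b, label_a=label_a, label_b=label_b)


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
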