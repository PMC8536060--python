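"""Pairwise LD from a reference panel and significance-ordered clumping.

LD is the squared Pearson correlation of genotype dosages in the panel
(composite genotypic LD — no phasing required). Clumping keeps, within
every group of correlated SNPs, only the most significant one: candidates
are visited in ascending p-value order and a SNP is retained only if its
panel r-squared with every already-retained SNP stays at or below the
threshold. This greedy keep-best pass is equivalent to repeatedly
excluding the less significant member of each high-LD pair until none
remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .cis import AssocResult
from .datatypes import GenotypeMatrix, SNPRecord

logger = logging.getLogger(__name__)


class MonomorphicInPanelError(ValueError):
    """SNP constant in the reference panel: LD and genotype proportions
    are undefined, so the SNP must be dropped from the model."""


@dataclass
class ReferencePanel:
    """An external genotype cohort used for LD and genotype proportions.

    Every SNP entering clumping or adjustment must be present and
    polymorphic here; the panel is assumed allele-harmonized with the
    training cohort.
    """

    genotypes: GenotypeMatrix
    label: str = "reference_panel"

    def dosages_for(self, snp: SNPRecord) -> np.ndarray | None:
        j = self.genotypes.locus_column(snp.chrom, snp.pos)
        return None if j is None else self.genotypes.dosage[:, j]

    def contains(self, snp: SNPRecord) -> bool:
        return self.dosages_for(snp) is not None


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples called for both SNPs; at least 3 shared
    called samples are required and both vectors must vary on that set.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise MonomorphicInPanelError("fewer than 3 shared called samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MonomorphicInPanelError("monomorphic_in_panel")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def clump_order_key(result: AssocResult):
    """Deterministic priority: ascending p, ties by (chrom, pos, snp_id)."""
    return (result.p, _chrom_sort_key(result.snp.chrom), result.snp.pos, result.snp.snp_id)


def clump(
    assoc: Sequence[AssocResult],
    panel: ReferencePanel,
    r2_threshold: float,
) -> List[AssocResult]:
    """Greedy LD pruning of association results against a reference panel.

    All input SNPs must be present and polymorphic in the panel (drop
    others beforehand). The retained set is maximal under the priority
    order: every pair of survivors has panel r-squared <= r2_threshold,
    and the most significant SNP of the input always survives. Output
    order follows the priority order.
    """
    ordered = sorted(assoc, key=clump_order_key)
    kept: List[AssocResult] = []
    kept_dosages: List[np.ndarray] = []
    for cand in ordered:
        d = panel.dosages_for(cand.snp)
        if d is None:
            raise KeyError(f"absent_from_panel: {cand.snp.snp_id}")
        if all(ld_r2(d, kd) <= r2_threshold for kd in kept_dosages):
            kept.append(cand)
            kept_dosages.append(d)
        else:
            logger.debug("clump: excluding %s (p=%.3g)", cand.snp.snp_id, cand.p)
    return kept
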