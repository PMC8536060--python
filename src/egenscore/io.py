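"""Readers and writers for every on-disk format, plus allele harmonization.

Formats
-------
* genotypes: VCF v4.x (GT field; read through cyvcf2) or a plain dosage
  TSV with one row per SNP, columns ``snp_id chrom pos effect_allele
  other_allele`` followed by one column per sample, ``.`` marking a
  missing genotype;
* expression: TSV, genes x samples, first column ``gene_id``;
* gene annotation: TSV with ``gene_id chrom start end strand``;
* trained models: TSV with one row per SNP weight and per-gene metadata
  in ``##model`` header lines, so that an empty (null) model still
  round-trips.

By convention the VCF ALT allele is the effect allele: every beta in a
model weighs the count of that allele.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import (
    AUTOSOMES,
    EqtlModel,
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    ModelWeight,
    SNPRecord,
)

logger = logging.getLogger(__name__)

MODEL_COLUMNS = [
    "gene_id",
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "adjustment",
    "framework",
]

_DOSAGE_META_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_dosages(path: Union[str, Path]) -> GenotypeMatrix:
    """Read a VCF into effect-allele dosages, counting the ALT allele.

    Only biallelic autosomal SNPs are kept; multi-allelic records,
    indels and sex-chromosome records are skipped with a logged warning.
    Missing genotypes (``./.``) become uncalled entries.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snps: List[SNPRecord] = []
    rows: List[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        chrom = _normalize_chrom(variant.CHROM)
        if chrom not in AUTOSOMES:
            n_skipped += 1
            continue
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", chrom, variant.POS)
            n_skipped += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            logger.warning("skipping non-SNP record %s:%s", chrom, variant.POS)
            n_skipped += 1
            continue
        # gts012=True: gt_types counts ALT alleles, 3 == uncalled
        dosage = variant.gt_types.astype(float)
        dosage[dosage == 3] = np.nan
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{chrom}:{variant.POS}"
        snps.append(
            SNPRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=variant.POS,
                effect_allele=alt,
                other_allele=ref,
            )
        )
        rows.append(dosage)
    if not snps:
        raise ValueError(f"{path}: no biallelic autosomal SNP records found")
    if n_skipped:
        logger.info("%s: skipped %d non-conforming records", path, n_skipped)
    return GenotypeMatrix(samples, snps, np.column_stack(rows))


def write_vcf(genotypes: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write dosages back to a minimal VCF v4.2 (GT field only).

    Dosage 0/1/2 maps to ``0/0``, ``0/1``, ``1/1``; uncalled to ``./.``.
    REF is the other allele, ALT the effect allele, so a round trip
    through :func:`read_vcf_dosages` preserves orientation.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.other_allele}\t"
                f"{snp.effect_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Dosage TSV
# ---------------------------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DOSAGE_META_COLUMNS + genotypes.sample_ids) + "\n")
        for j, snp in enumerate(genotypes.snps):
            vals = [
                "." if np.isnan(d) else str(int(d)) for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"{snp.snp_id}\t{snp.chrom}\t{snp.pos}\t{snp.effect_allele}\t"
                f"{snp.other_allele}\t" + "\t".join(vals) + "\n"
            )


def read_dosage_tsv(path: Union[str, Path]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _DOSAGE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage TSV missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in _DOSAGE_META_COLUMNS]
    snps = [
        SNPRecord(
            snp_id=str(r.snp_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
        )
        for r in df.itertuples()
    ]
    dosage = (
        df[sample_ids].replace(".", np.nan).apply(pd.to_numeric).to_numpy(float).T
    )
    return GenotypeMatrix(sample_ids, snps, dosage)


# ---------------------------------------------------------------------------
# Expression and gene tables
# ---------------------------------------------------------------------------

def write_expression_tsv(expression: ExpressionMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        expression.values, index=expression.gene_ids, columns=expression.sample_ids
    )
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: Union[str, Path]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(float)
    )


def write_gene_table(genes: Sequence[GeneRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path: Union[str, Path]) -> List[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Model TSV
# ---------------------------------------------------------------------------

def write_model_tsv(
    models: Union[EqtlModel, Sequence[EqtlModel]], path: Union[str, Path]
) -> None:
    """Serialize one or more per-gene models losslessly.

    Per-gene metadata (framework, alpha, seed, training label) goes into
    ``##model`` header lines so a null model with no weight rows still
    round-trips field-by-field.
    """
    if isinstance(models, EqtlModel):
        models = [models]
    with open(path, "w") as fh:
        for model in models:
            meta = "\t".join(
                f"{k}={model.metadata[k]}" for k in sorted(model.metadata)
            )
            fh.write(
                f"##model\tgene_id={model.gene_id}\tframework={model.framework}"
                + ("\t" + meta if meta else "")
                + "\n"
            )
        fh.write("\t".join(MODEL_COLUMNS) + "\n")
        for model in models:
            for w in model.weights:
                fh.write(
                    f"{model.gene_id}\t{w.snp.snp_id}\t{w.snp.chrom}\t{w.snp.pos}\t"
                    f"{w.snp.effect_allele}\t{w.snp.other_allele}\t"
                    f"{w.beta!r}\t{w.adjustment!r}\t{model.framework}\n"
                )


def _parse_meta_value(value: str) -> object:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_model_tsv(path: Union[str, Path]) -> List[EqtlModel]:
    """Read a model TSV back into :class:`EqtlModel` objects, in file order."""
    meta_lines: List[Dict[str, str]] = []
    body: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##model"):
                fields = line.rstrip("\n").split("\t")[1:]
                meta_lines.append(dict(f.split("=", 1) for f in fields if "=" in f))
            else:
                body.append(line)
    if not body:
        raise ValueError(f"{path}: model TSV has no header row")
    header = body[0].rstrip("\n").split("\t")
    missing = [c for c in MODEL_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: model TSV missing columns {missing}")
    models: Dict[str, EqtlModel] = {}
    for meta in meta_lines:
        gene_id = meta.pop("gene_id")
        framework = meta.pop("framework")
        models[gene_id] = EqtlModel(
            gene_id=gene_id,
            framework=framework,
            metadata={k: _parse_meta_value(v) for k, v in meta.items()},
        )
    col = {c: header.index(c) for c in MODEL_COLUMNS}
    for line in body[1:]:
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        gene_id = f[col["gene_id"]]
        try:
            beta = float(f[col["beta"]])
            adjustment = float(f[col["adjustment"]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric beta/adjustment: {exc}") from exc
        snp = SNPRecord(
            snp_id=f[col["snp_id"]],
            chrom=f[col["chrom"]],
            pos=int(f[col["pos"]]),
            effect_allele=f[col["effect_allele"]],
            other_allele=f[col["other_allele"]],
        )
        if gene_id not in models:
            models[gene_id] = EqtlModel(gene_id=gene_id, framework=f[col["framework"]])
        models[gene_id].weights.append(
            ModelWeight(snp=snp, beta=beta, adjustment=adjustment)
        )
    return list(models.values())


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(
    reference_snps: Sequence[SNPRecord],
    target: GenotypeMatrix,
    drop_strand_ambiguous: bool = False,
) -> GenotypeMatrix:
    """Re-orient a cohort's dosages to a reference set of effect alleles.

    SNPs are matched by (chrom, pos). Where the target counts the
    opposite allele of the same pair, dosages are flipped (2 - d);
    loci absent from the target or with a different allele pair are
    dropped with a warning. The returned matrix carries the reference
    SNP records (hence reference effect-allele orientation) in
    reference order, so downstream betas apply directly.
    """
    kept_snps: List[SNPRecord] = []
    columns: List[np.ndarray] = []
    n_flipped = n_dropped = 0
    for snp in reference_snps:
        j = target.locus_column(snp.chrom, snp.pos)
        if j is None:
            n_dropped += 1
            logger.warning("harmonize: %s absent from target cohort", snp.snp_id)
            continue
        tgt = target.snps[j]
        if tgt.alleles != snp.alleles:
            n_dropped += 1
            logger.warning(
                "harmonize: %s allele mismatch %s vs %s",
                snp.snp_id,
                sorted(snp.alleles),
                sorted(tgt.alleles),
            )
            continue
        if drop_strand_ambiguous and snp.strand_ambiguous:
            n_dropped += 1
            logger.warning("harmonize: %s strand-ambiguous, dropped", snp.snp_id)
            continue
        col = target.dosage[:, j]
        if tgt.effect_allele != snp.effect_allele:
            col = 2.0 - col
            n_flipped += 1
        kept_snps.append(snp)
        columns.append(col)
    if n_flipped or n_dropped:
        logger.info(
            "harmonize: %d SNPs kept, %d flipped, %d dropped",
            len(kept_snps),
            n_flipped,
            n_dropped,
        )
    dosage = (
        np.column_stack(columns)
        if columns
        else np.empty((target.n_samples, 0), dtype=float)
    )
    return GenotypeMatrix(target.sample_ids, kept_snps, dosage)
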