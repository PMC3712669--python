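"""Plain-text readers and writers for the pipeline's interchange formats.

Association summaries travel as tab-separated tables in the PLINK
``.assoc`` style (columns SNP, CHR, BP, A1, A2, OR, SE, P, N); floats are
written with six significant digits, which round-trips losslessly at
that precision. Genotypes can be exported as a minimal VCF v4.2 or as a
transposed plain-text matrix; phenotypes/covariates, gene annotations
and pathway gene lists are tab-separated text.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import StudyData
from .types import GeneAnnotation, PathwayDefinition, SnpRecord

__all__ = [
    "write_assoc",
    "read_assoc",
    "write_vcf",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "attach_phenotypes",
    "write_blocks",
    "read_blocks",
    "write_phenotypes",
    "read_phenotypes",
    "write_annotations",
    "read_annotations",
    "write_annotations_bed",
    "write_pathway",
    "read_pathway",
]

_ASSOC_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "OR", "SE", "P", "N"]


def write_assoc(table: pd.DataFrame, path: str) -> None:
    """Write an association (or meta-analysis) summary table."""
    out = table.copy()
    cols = [c for c in _ASSOC_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols and c != "NOTE"]
    out = out[cols]
    for c in ("OR", "SE", "P"):
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.6g}" if np.isfinite(v) else "NA")
    out.to_csv(path, sep="\t", index=False)


def read_assoc(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str},
                     na_values=["NA"])
    missing = [c for c in _ASSOC_COLUMNS if c not in df.columns and c != "A2"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _gt_string(dosage: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(dosage)]


def write_vcf(study: StudyData, path: str, sample_prefix: str = "S") -> None:
    """Minimal VCF v4.2 export of a cohort's genotypes.

    Diploid dosage coding is kept as stored, so hemizygous male X
    genotypes (coded 0/2) are written as homozygous diploid calls.
    """
    samples = [f"{sample_prefix}{i + 1:05d}" for i in range(study.n_subjects)]
    chroms = []
    for s in study.snps:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathperm\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, snp in enumerate(study.snps):
            gts = "\t".join(_gt_string(d) for d in study.genotypes[:, j])
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotype_matrix(study: StudyData, path: str) -> None:
    """Transposed plain-text dosage matrix: one row per SNP, one column
    per subject, preceded by SNP metadata columns."""
    meta_cols = pd.DataFrame(
        {
            "SNP": [s.id for s in study.snps],
            "CHR": [s.chrom for s in study.snps],
            "BP": [s.pos for s in study.snps],
            "A1": [s.alt for s in study.snps],
            "A2": [s.ref for s in study.snps],
        }
    )
    geno = pd.DataFrame(
        study.genotypes.T,
        columns=[f"S{i + 1:05d}" for i in range(study.n_subjects)],
    )
    pd.concat([meta_cols, geno], axis=1).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str) -> StudyData:
    """Rebuild a genotype container from a transposed dosage matrix.

    Phenotype fields are left empty; combine with
    :func:`read_phenotypes` to restore a full cohort.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    sample_cols = [c for c in df.columns if c not in ("SNP", "CHR", "BP", "A1", "A2")]
    geno = df[sample_cols].to_numpy(dtype=np.int8).T
    freqs = geno.mean(axis=0) / 2.0
    snps = [
        SnpRecord(row.SNP, row.CHR, int(row.BP), row.A2, row.A1, float(f))
        for row, f in zip(df.itertuples(), freqs)
    ]
    n = geno.shape[0]
    return StudyData(
        name=os.path.splitext(os.path.basename(path))[0],
        snps=snps,
        genotypes=geno,
        status=np.zeros(n, dtype=bool),
        sex=np.array(["female"] * n),
        age=np.zeros(n),
        site=np.zeros(n, dtype=int),
        iop=np.full(n, np.nan),
    )


def attach_phenotypes(study: StudyData, pheno: pd.DataFrame) -> StudyData:
    """Attach a phenotype table (from :func:`read_phenotypes`) to a
    genotype container, aligned by row order."""
    if len(pheno) != study.n_subjects:
        raise ValueError("phenotype table does not match the genotype matrix")
    return StudyData(
        name=study.name,
        snps=study.snps,
        genotypes=study.genotypes,
        status=pheno["STATUS"].to_numpy(dtype=bool),
        sex=pheno["SEX"].to_numpy(dtype=object).astype(str),
        age=pheno["AGE"].to_numpy(dtype=float),
        site=pheno["SITE"].to_numpy(dtype=int),
        iop=pheno["IOP"].to_numpy(dtype=float),
    )


def write_blocks(blocks: Sequence["LdBlock"], path: str) -> None:
    """LD blocks as a long table: one row per member SNP."""
    rows = []
    for i, b in enumerate(blocks):
        for s in b.snps:
            rows.append((i, b.chrom, s, b.start, b.end))
    pd.DataFrame(rows, columns=["BLOCK", "CHR", "SNP", "START", "END"]).to_csv(
        path, sep="\t", index=False
    )


def read_blocks(path: str) -> List["LdBlock"]:
    from .types import LdBlock

    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    out = []
    for _, sub in df.groupby("BLOCK", sort=True):
        out.append(
            LdBlock(
                chrom=str(sub["CHR"].iloc[0]),
                snps=tuple(sub["SNP"]),
                start=int(sub["START"].iloc[0]),
                end=int(sub["END"].iloc[0]),
            )
        )
    return out


def write_phenotypes(study: StudyData, path: str) -> None:
    """Phenotype + covariate table, one row per subject."""
    pd.DataFrame(
        {
            "ID": [f"S{i + 1:05d}" for i in range(study.n_subjects)],
            "STATUS": study.status.astype(int),
            "SEX": study.sex,
            "AGE": [f"{a:.6g}" for a in study.age],
            "SITE": study.site,
            "IOP": [f"{v:.6g}" if np.isfinite(v) else "NA" for v in study.iop],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_annotations(genes: Sequence[GeneAnnotation], path: str) -> None:
    """Native annotation table: 1-based inclusive start/end."""
    pd.DataFrame(
        {
            "SYMBOL": [g.symbol for g in genes],
            "CHR": [g.chrom for g in genes],
            "START": [g.start for g in genes],
            "END": [g.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str) -> List[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"SYMBOL": str, "CHR": str})
    return [
        GeneAnnotation(row.SYMBOL, row.CHR, int(row.START), int(row.END))
        for row in df.itertuples()
    ]


def write_annotations_bed(genes: Sequence[GeneAnnotation], path: str) -> None:
    """BED export: 0-based half-open intervals (start-1, end)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


def write_pathway(pathway: PathwayDefinition, path: str) -> None:
    """One gene symbol per line."""
    with open(path, "w") as fh:
        for g in pathway.genes:
            fh.write(g + "\n")


def read_pathway(path: str, name: Optional[str] = None, flank: int = 50_000) -> PathwayDefinition:
    with open(path) as fh:
        genes = tuple(line.strip() for line in fh if line.strip())
    return PathwayDefinition(
        name=name or os.path.splitext(os.path.basename(path))[0],
        genes=genes,
        flank=flank,
    )
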