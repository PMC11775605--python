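"""Plain-text readers/writers: counts, metadata, class tables, VCF."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GenotypeMatrix, validate_metadata


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts(counts: CountMatrix | pd.DataFrame, path: str | Path) -> None:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_metadata(meta)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_annotation(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, chromosome) -> Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}
_BASES = ("A", "C", "G", "T")


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal single-contig VCF with GT:DP:GQ genotype fields."""
    samples = list(genotypes.lineage_ids)
    dosage = genotypes.dosage.to_numpy()
    depth = (
        genotypes.depth.to_numpy()
        if genotypes.depth is not None
        else np.full_like(dosage, 100)
    )
    qual = (
        genotypes.quality.to_numpy()
        if genotypes.quality is not None
        else np.full_like(dosage, 99)
    )
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for i, snp_id in enumerate(genotypes.dosage.index):
        ref, alt = _BASES[i % 4], _BASES[(i + 1) % 4]
        fields = [
            f"{_GT[int(dosage[i, j])]}:{int(depth[i, j])}:{int(qual[i, j])}"
            for j in range(len(samples))
        ]
        lines.append(
            f"1\t{i + 1}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:GQ\t"
            + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")
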