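"""Readers and writers for the pipeline's plain-text table formats.

All tables are TSV/CSV with a fixed column contract:

* intensity table (TSV): ``probe_id, array_id, cy3, cy5``
* design file (TSV): ``array_id, cy3_sample, cy5_sample, replicate``
* contrast table (TSV): ``probe_id, contrast, log2FC, p, q, flag``
* genotype table (CSV): ``specimen_id, site, round, status,
  genotype_1014, genotype_1575``
* qPCR plate (CSV): ``replicate_id, population_year, gene, role, Ct,
  efficiency``
* probe->gene map (TSV): ``probe_id, gene_id``

A minimal two-site VCF export of the genotype table is provided for
interoperability with variant tooling.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import HybridizationDesign

__all__ = [
    "read_intensities",
    "write_intensities",
    "read_design",
    "write_design",
    "read_contrasts",
    "write_contrasts",
    "read_genotypes",
    "write_genotypes",
    "read_plate",
    "write_plate",
    "read_probe_gene_map",
    "write_probe_gene_map",
    "write_genotypes_vcf",
]


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")
    return df


def read_intensities(path: str | Path) -> pd.DataFrame:
    return _require(
        pd.read_csv(path, sep="\t"),
        ("probe_id", "array_id", "cy3", "cy5"),
        "intensity table",
    )


def write_intensities(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> HybridizationDesign:
    frame = _require(
        pd.read_csv(path, sep="\t"),
        ("array_id", "cy3_sample", "cy5_sample", "replicate"),
        "design file",
    )
    return HybridizationDesign.from_frame(frame)


def write_design(design: HybridizationDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_contrasts(path: str | Path) -> pd.DataFrame:
    df = _require(
        pd.read_csv(path, sep="\t"),
        ("probe_id", "contrast", "log2FC", "p", "q"),
        "contrast table",
    )
    if "flag" in df.columns:
        df["flag"] = df["flag"].fillna("")
    return df


def write_contrasts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    return _require(
        pd.read_csv(path),
        ("specimen_id", "site", "round", "status", "genotype_1014", "genotype_1575"),
        "genotype table",
    )


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_plate(path: str | Path) -> pd.DataFrame:
    return _require(
        pd.read_csv(path),
        ("replicate_id", "population_year", "gene", "role", "Ct", "efficiency"),
        "qPCR plate",
    )


def write_plate(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_probe_gene_map(path: str | Path) -> pd.DataFrame:
    return _require(
        pd.read_csv(path, sep="\t"), ("probe_id", "gene_id"), "probe->gene map"
    )


def write_probe_gene_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["probe_id", "gene_id"]].to_csv(path, sep="\t", index=False)


_VCF_GT = {
    ("LL",): "0/0", ("LF",): "0/1", ("FF",): "1/1",
    ("NN",): "0/0", ("NY",): "0/1", ("YY",): "1/1",
}


def write_genotypes_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Write the two kdr sites as a minimal diploid VCF (sites 1014, 1575).

    Positions are the codon numbers on a placeholder contig ``vgsc``;
    alleles are coded L->F and N->Y as REF->ALT single-base placeholders
    with the amino-acid change in INFO.  Unphased genotypes only.
    """
    specimens = df["specimen_id"].tolist()
    lines = [
        "##fileformat=VCFv4.2",
        '##contig=<ID=vgsc>',
        '##INFO=<ID=AAC,Number=1,Type=String,Description="Amino acid change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(specimens),
    ]
    site_specs = [
        ("1014", "L1014F", "genotype_1014"),
        ("1575", "N1575Y", "genotype_1575"),
    ]
    for pos, aac, col in site_specs:
        gts = [_VCF_GT[(g,)] for g in df[col]]
        lines.append(
            f"vgsc\t{pos}\t{aac}\tA\tT\t.\tPASS\tAAC={aac}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
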