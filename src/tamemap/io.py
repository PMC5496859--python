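"""Readers and writers for the plain-text interchange formats.

Everything is tab-separated text: founder panels, genetic maps, pedigrees,
genotype matrices, phenotype tables, BED interval files, chromosome-size
files, and orthologue maps.  A minimal PLINK text (.map/.ped) ingestion
path is provided for founder panels delivered in that dialect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_panel import META_COLUMNS, FounderPanel, GenotypeMatrix
from .pedigree_gene_drop import PED_COLUMNS, GeneticMap, Pedigree
from .synteny_overlap import IntervalSet, OrthologueMap

# --- founder panel ----------------------------------------------------------


def read_panel_tsv(path, strains: list[str] | None = None) -> FounderPanel:
    """Panel TSV: chrom, snp_id, bp, cM, then one allele column per strain."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if strains is None:
        strains = [c for c in df.columns if c not in META_COLUMNS]
    return FounderPanel(list(strains), df)


def write_panel_tsv(panel: FounderPanel, path) -> None:
    panel.snps.to_csv(path, sep="\t", index=False)


def read_plink_panel(map_path, ped_path) -> FounderPanel:
    """Founder panel from PLINK text files (.map + .ped).

    The .map file gives chrom, snp_id, cM, bp; each .ped row is one strain:
    FID IID PAT MAT SEX PHENO then two space-separated allele columns per
    SNP.  Inbred founders are expected to be homozygous; heterozygous calls
    are treated as missing, as is "0".
    """
    m = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cM", "bp"],
        dtype={"chrom": str},
    )
    strains = []
    calls = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            strains.append(parts[1])
            geno = parts[6:]
            if len(geno) != 2 * len(m):
                raise ValueError(
                    f"{ped_path}: row {parts[1]} has {len(geno)} allele fields, "
                    f"expected {2 * len(m)}"
                )
            a1 = np.array(geno[0::2])
            a2 = np.array(geno[1::2])
            call = np.where((a1 == a2) & (a1 != "0"), a1, "N")
            calls.append(call)
    df = m[["chrom", "snp_id", "bp", "cM"]].copy()
    for s, c in zip(strains, calls):
        df[s] = c
    return FounderPanel(strains, df)


# --- genetic map ------------------------------------------------------------


def read_map_tsv(path, chrom_lengths: dict[str, float] | None = None) -> GeneticMap:
    """Map TSV: chrom, snp_id, bp, cM.  Lengths default to each
    chromosome's maximum cM position."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): float(sub["cM"].max()) for c, sub in df.groupby("chrom", sort=False)
        }
    return GeneticMap(chrom_lengths, df[["chrom", "snp_id", "bp", "cM"]])


def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.snps.to_csv(path, sep="\t", index=False)


# --- pedigree ---------------------------------------------------------------


def read_pedigree_tsv(path) -> Pedigree:
    """Pedigree TSV with "0" (or blank) for unknown parents (founders only)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pedigree file lacks columns {missing}")
    df["generation"] = df["generation"].astype(int)
    for col in ("selected", "breeder"):
        df[col] = df[col].str.lower().isin(("1", "true", "t", "yes"))
    for col in ("sire", "dam"):
        df[col] = df[col].replace("0", "")
    bad = df[(df["generation"] > 0) & ((df["sire"] == "") | (df["dam"] == ""))]
    if not bad.empty:
        raise ValueError(
            f"non-founders with unknown parents: {list(bad['id'].head())}"
        )
    return Pedigree(df[PED_COLUMNS])


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    out = ped.table.copy()
    for col in ("selected", "breeder"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


# --- genotypes --------------------------------------------------------------


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Genotype TSV: first column individual id, then one 0/1/2/NA column per SNP."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(values=df.astype(float))


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.values.copy()
    out.index.name = "individual"
    out.to_csv(path, sep="\t", na_rep="NA")


# --- phenotypes -------------------------------------------------------------


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "group": str})
    if "selected" in df.columns and df["selected"].dtype != bool:
        df["selected"] = df["selected"].astype(str).str.lower().isin(("1", "true", "t", "yes"))
    return df


# --- intervals, sizes, orthologues -----------------------------------------


def read_bed(path, genome: str = "") -> IntervalSet:
    """Three- or four-column BED (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "label"][: df.shape[1]]
    return IntervalSet(genome=genome, intervals=df)


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", index=False, header=False)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_orthologue_map(path) -> OrthologueMap:
    """Orthologue TSV: gene, chrom_a, start_a, end_a, chrom_b, start_b, end_b."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    need = ["gene", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"orthologue file lacks columns {missing}")
    return OrthologueMap(records=df[need])
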