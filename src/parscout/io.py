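"""Readers and writers for the package's on-disk interchange formats.

All coordinates in files are 1-based inclusive (VCF/GFF3 convention) except
BED, which is 0-based half-open; in memory everything is 0-based half-open.
VCF input is parsed with cyvcf2; writing uses plain-text emission because the
records are simple and must encode per-individual mixed ploidy (haploid
female calls on the differentiated Z are written as single-allele genotypes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen import MISSING, HaplotypePanel
from .sim.genotypes import GenotypeTable

# --------------------------------------------------------------------------
# FASTA / GFF3 / BED
# --------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: pd.DataFrame, path) -> None:
    """Emit the simulator's feature table (gene/mRNA/CDS) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            if row["type"] == "gene":
                attrs = f"ID={row['feature_id']}"
            else:
                attrs = f"ID={row['feature_id']};Parent={row['parent']}"
            fh.write(
                "\t".join(
                    [
                        row["scaffold"],
                        row["source"],
                        row["type"],
                        str(row["start"]),
                        str(row["end"]),
                        ".",
                        row["strand"],
                        "0" if row["type"] == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED3(+name): expects columns scaffold, start, end [, name]; 0-based half-open."""
    cols = ["scaffold", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["scaffold", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] > 3:
        df = df.rename(columns={"col3": "name"})
    return df


# --------------------------------------------------------------------------
# genotype tables
# --------------------------------------------------------------------------


def write_genotypes_tsv(gt: GenotypeTable, path) -> None:
    out = gt.markers[["marker", "scaffold", "position", "role"]].merge(
        gt.calls.reset_index(), on="marker"
    )
    out.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    meta_cols = ["marker", "scaffold", "position", "role"]
    markers = df[meta_cols].copy()
    # restore linkage-unit bookkeeping (autosomal scaffolds standalone, Z shared)
    markers["chrom"] = np.where(markers["role"] == "autosome", markers["scaffold"], "Z")
    markers["chrom_pos"] = markers["position"] - 1
    calls = df.drop(columns=[c for c in meta_cols if c != "marker"]).set_index("marker")
    return GenotypeTable(markers, calls)


# --------------------------------------------------------------------------
# haplotype panel (phased VCF + ploidy + groups)
# --------------------------------------------------------------------------


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    ids = panel.individuals["id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaffold in panel.sites["scaffold"].unique():
            length = int(panel.sites.loc[panel.sites["scaffold"] == scaffold, "position"].max())
            fh.write(f"##contig=<ID={scaffold},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for k, site in panel.sites.iterrows():
            calls = []
            for i in range(len(ids)):
                a0, a1 = panel.alleles[i, 0, k], panel.alleles[i, 1, k]
                calls.append(str(a0) if a1 == MISSING else f"{a0}|{a1}")
            fh.write(
                f"{site['scaffold']}\t{site['position']}\t.\t{site['ref']}\t{site['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_ploidy_tsv(panel: HaplotypePanel, path) -> None:
    panel.ploidy.rename_axis("id").to_csv(path, sep="\t")


def write_groups_tsv(panel: HaplotypePanel, path) -> None:
    panel.individuals.to_csv(path, sep="\t", index=False)


def read_panel_vcf(vcf_path, ploidy_path, groups_path) -> HaplotypePanel:
    """Load a phased VCF plus ploidy-map and group-label sidecars."""
    from cyvcf2 import VCF

    individuals = pd.read_csv(groups_path, sep="\t", dtype=str)
    ploidy = pd.read_csv(ploidy_path, sep="\t", index_col="id")
    vcf = VCF(str(vcf_path))
    if list(vcf.samples) != individuals["id"].tolist():
        raise ValueError("VCF samples do not match the groups file")
    site_rows, allele_cols = [], []
    for variant in vcf:
        site_rows.append(
            {
                "scaffold": variant.CHROM,
                "position": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
            }
        )
        col = np.full((len(vcf.samples), 2), MISSING, dtype=np.int8)
        for i, call in enumerate(variant.genotypes):  # [a0, (a1,) phased-flag]
            alleles_i = call[:-1]
            col[i, 0] = alleles_i[0]
            if len(alleles_i) > 1 and alleles_i[1] >= 0:
                col[i, 1] = alleles_i[1]
        allele_cols.append(col)
    sites = pd.DataFrame(site_rows)
    alleles = (
        np.stack(allele_cols, axis=2) if allele_cols else np.zeros((len(individuals), 2, 0), np.int8)
    )
    return HaplotypePanel(sites=sites, alleles=alleles, individuals=individuals, ploidy=ploidy)
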