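"""Softmasked sequence, gene annotation and expression fixtures.

These supply the characterization stage with inputs whose summary statistics
are controlled: per-scaffold GC fraction, softmasked (repeat) fraction, gene
density, and a per-role multiplicative male:female expression effect.  Gene
counts are deterministic (density x length, rounded) so that regional gene
densities are exact; base composition and repeat placement are stochastic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import stage_rng
from .config import SimConfig

_REPEAT_MEAN_LEN = 500  # bp, geometric interval lengths for masked runs


def simulate_sequences(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Softmasked FASTA sequences, one per scaffold of the genome plan.

    GC content and the lowercase (repeat-masked) fraction match the per-role
    targets in expectation; masked runs have geometric lengths of mean 500 bp.
    """
    if rng is None:
        rng = stage_rng(config.seed, "sequences")
    out = {}
    for scaf in config.genome_plan:
        gc = config.gc_target[scaf.role]
        bases = np.where(
            rng.random(scaf.length) < gc,
            rng.choice(np.array(["G", "C"]), scaf.length),
            rng.choice(np.array(["A", "T"]), scaf.length),
        )
        mask = np.zeros(scaf.length, dtype=bool)
        target = config.repeat_target[scaf.role] * scaf.length
        covered = 0
        while covered < target:
            start = rng.integers(0, scaf.length)
            run = min(1 + rng.geometric(1.0 / _REPEAT_MEAN_LEN), scaf.length - start)
            newly = int((~mask[start : start + run]).sum())
            mask[start : start + run] = True
            covered += newly
        seq = np.where(mask, np.char.lower(bases), bases)
        out[scaf.name] = "".join(seq.tolist())
    return out


def simulate_annotation(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene/mRNA/CDS feature table (GFF3-shaped; 1-based inclusive coordinates).

    Per scaffold, the gene count is round(genes_per_mb x length_Mb); genes are
    non-overlapping, 4 kb long with three CDS exons totalling ~1.4 kb.
    """
    if rng is None:
        rng = stage_rng(config.seed, "sequences")
    gene_len, cds_lens = 4_000, (500, 500, 375)
    exon_offsets = (0, 1_500, 3_000)
    rows = []
    for scaf in config.genome_plan:
        n_genes = int(round(config.genes_per_mb[scaf.role] * scaf.length / 1e6))
        n_genes = min(n_genes, scaf.length // (2 * gene_len))
        if n_genes == 0:
            continue
        slot = scaf.length // max(n_genes, 1)
        for g in range(n_genes):
            margin = max(slot - gene_len, 1)
            start = g * slot + int(rng.integers(0, margin)) + 1  # 1-based
            gid = f"{scaf.name}_gene{g + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((scaf.name, "parscout_sim", "gene", start, start + gene_len - 1, strand, gid, gid))
            mid = f"{gid}.t1"
            rows.append((scaf.name, "parscout_sim", "mRNA", start, start + gene_len - 1, strand, mid, gid))
            for off, clen in zip(exon_offsets, cds_lens):
                rows.append(
                    (scaf.name, "parscout_sim", "CDS", start + off, start + off + clen - 1, strand, f"{mid}.cds", mid)
                )
    return pd.DataFrame(
        rows, columns=["scaffold", "source", "type", "start", "end", "strand", "feature_id", "parent"]
    )


def simulate_expression(
    config: SimConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(expression matrix, sample metadata) for all annotated genes.

    Samples are tissue x sex x replicate; values are linear-scale expression
    units.  Genes on scaffolds of a role with sex effect r have male means
    r-fold the female means in every shared tissue.  Gonadal samples exist
    only for the matching sex (testis: males, ovary: females).
    """
    if rng is None:
        rng = stage_rng(config.seed, "expression")
    plan = config.expression_plan
    role_of = {s.name: s.role for s in config.genome_plan}
    genes = annotation[annotation["type"] == "gene"]

    samples = []
    for tissue in plan.tissues:
        for sex in ("M", "F"):
            if tissue == "testis" and sex == "F":
                continue
            if tissue == "ovary" and sex == "M":
                continue
            for rep in range(1, plan.replicates_per_sex + 1):
                samples.append({"sample": f"{tissue}_{sex}{rep}", "tissue": tissue, "sex": sex})
    meta = pd.DataFrame(samples)

    values = np.empty((len(genes), len(meta)))
    for gi, (_, gene) in enumerate(genes.iterrows()):
        ratio = plan.sex_effect[role_of[gene["scaffold"]]]
        tissue_mean = {
            t: plan.mean_log2_expression + rng.normal(0, plan.sd_log2_expression) for t in plan.tissues
        }
        for si, sample in meta.iterrows():
            mu = tissue_mean[sample["tissue"]]
            if sample["sex"] == "M":
                mu += np.log2(ratio)
            values[gi, si] = 2.0 ** (mu + rng.normal(0, plan.noise_sd_log2))
    matrix = pd.DataFrame(values, index=genes["feature_id"].to_numpy(), columns=meta["sample"].to_numpy())
    matrix.index.name = "gene"
    return matrix, meta
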