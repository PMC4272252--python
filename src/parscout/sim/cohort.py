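"""End-to-end cohort assembly: every input the downstream stages consume."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .._util import stage_rng, tile_windows
from ..popgen import HaplotypePanel
from .config import SimConfig
from .depth import simulate_read_depth
from .features import simulate_annotation, simulate_expression, simulate_sequences
from .genotypes import GenotypeTable, simulate_zw_genotypes
from .pedigree import Pedigree, simulate_pedigree


@dataclass
class SimulatedCohort:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeTable
    truth_map: pd.DataFrame
    depth: pd.DataFrame
    haplotypes: HaplotypePanel
    sequences: dict[str, str]
    annotation: pd.DataFrame
    expression: pd.DataFrame
    expression_samples: pd.DataFrame
    truth_labels: pd.DataFrame  # scaffold, start, end, name (= role), per window


def truth_label_windows(config: SimConfig, window_size: int = 200_000) -> pd.DataFrame:
    rows = [
        {"scaffold": s.name, "start": start, "end": end, "name": s.role}
        for s in config.genome_plan
        for start, end in tile_windows(s.length, window_size)
    ]
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig, skip: tuple[str, ...] = ()) -> SimulatedCohort:
    """Generate the full cohort under one seed; heavy stages can be skipped by name."""
    ped = simulate_pedigree(config)
    genotypes = truth = depth = panel = None
    sequences, annotation = {}, pd.DataFrame()
    expression = pd.DataFrame()
    samples = pd.DataFrame()
    if "genotypes" not in skip:
        genotypes, truth = simulate_zw_genotypes(ped, config)
    if "depth" not in skip:
        depth = simulate_read_depth(config)
    if "haplotypes" not in skip:
        panel = simulate_haplotypes_all(config)
    if "features" not in skip:
        sequences = simulate_sequences(config)
        annotation = simulate_annotation(config)
        expression, samples = simulate_expression(config, annotation)
    return SimulatedCohort(
        config=config,
        pedigree=ped,
        genotypes=genotypes,
        truth_map=truth,
        depth=depth,
        haplotypes=panel,
        sequences=sequences,
        annotation=annotation,
        expression=expression,
        expression_samples=samples,
        truth_labels=truth_label_windows(config),
    )


def simulate_haplotypes_all(config: SimConfig) -> HaplotypePanel:
    from .haplotypes import simulate_haplotypes

    return simulate_haplotypes(config, rng=stage_rng(config.seed, "haplotypes"))


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write every cohort component; returns the path of each artifact."""
    from ..io import (
        write_bed,
        write_fasta,
        write_genotypes_tsv,
        write_gff3,
        write_groups_tsv,
        write_panel_vcf,
        write_ploidy_tsv,
    )
    from .depth import write_depth_tsv
    from .pedigree import write_pedigree_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_pedigree_tsv(cohort.pedigree, _p("pedigree.tsv"))
    if cohort.genotypes is not None:
        write_genotypes_tsv(cohort.genotypes, _p("genotypes.tsv"))
        cohort.truth_map.to_csv(_p("truth_map.tsv"), sep="\t", index=False)
    if cohort.depth is not None:
        write_depth_tsv(cohort.depth, _p("depth.tsv"))
    if cohort.haplotypes is not None:
        write_panel_vcf(cohort.haplotypes, _p("haplotypes.vcf"))
        write_ploidy_tsv(cohort.haplotypes, _p("ploidy.tsv"))
        write_groups_tsv(cohort.haplotypes, _p("groups.tsv"))
    if cohort.sequences:
        write_fasta(cohort.sequences, _p("genome.fa"))
        write_gff3(cohort.annotation, _p("annotation.gff3"))
        cohort.expression.to_csv(_p("expression.tsv"), sep="\t")
        cohort.expression_samples.to_csv(_p("expression_samples.tsv"), sep="\t", index=False)
    write_bed(cohort.truth_labels, _p("truth_labels.bed"))
    scaffolds = pd.DataFrame(
        [{"scaffold": s.name, "length": s.length, "role": s.role} for s in cohort.config.genome_plan]
    )
    scaffolds.to_csv(_p("scaffolds.tsv"), sep="\t", index=False)
    return paths
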