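"""Orchestration: simulate -> linkage -> coverage -> popgen -> characterize.

The final report aggregates, per Z scaffold, the independent lines of
evidence a PAR call rests on: significant linkage to the differentiated-Z
anchor markers with observed female recombination, equal male/female
sequencing depth, and the presence of heterozygous females.  Only when all
lines agree is a scaffold called PAR; disagreement yields "conflicting"
with the evidence retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covscan as cov
from . import linkage as lk
from .charext import gc_repeat_windows, gene_summary, mf_expression_ratio, expression_tau
from .popgen import window_scan
from .sim import SimConfig, Scaffold, simulate_cohort, write_cohort
from .sim.config import ROLE_AUTOSOME, ROLE_PAR, ROLE_Z_DIFF

log = logging.getLogger("parscout.pipeline")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    lod_threshold: float = 3.0
    map_function: str = "haldane"
    gap_padding: int = 5_000
    window_size: int = 200_000
    coverage_tolerance: float = 0.25
    hotspot_fold: float = 10.0
    popgen_window_sizes: tuple[int, ...] = (20_000, 630_000)
    ld_max_dist: int = 20_000
    max_anchors: int = 20
    stages: tuple[str, ...] = ("linkage", "coverage", "popgen", "characterize")
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        plan = sim_raw.pop("genome_plan", None)
        if plan is not None:
            sim_raw["genome_plan"] = tuple(Scaffold(**s) for s in plan)
        for key in ("pi_target", "df_target", "alpha_ld"):
            if key in sim_raw:
                sim_raw[key] = dict(sim_raw[key])
        sim = SimConfig(**sim_raw)
        for tup_key in ("popgen_window_sizes", "stages"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(sim=sim, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages on a simulated cohort; return the report."""
    report: dict = {"seed": config.sim.seed, "scaffolds": {}, "stages": list(config.stages)}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("simulating cohort (seed=%d)", config.sim.seed)
    cohort = simulate_cohort(config.sim)
    if outdir:
        write_cohort(cohort, outdir / "inputs")

    roles = {s.name: s.role for s in config.sim.genome_plan}
    evidence: dict[str, dict] = {
        s.name: {} for s in config.sim.genome_plan if s.role in (ROLE_PAR, ROLE_Z_DIFF)
    }

    gmap = None
    if "linkage" in config.stages:
        gmap, linkage_tables = _linkage_stage(config, cohort, evidence)
        report["linkage"] = linkage_tables
        if outdir and gmap is not None:
            gmap.table.to_csv(outdir / "genetic_map.tsv", sep="\t", index=False)

    if "coverage" in config.stages:
        windows, verdicts = _coverage_stage(config, cohort, evidence)
        report["coverage"] = {
            "n_windows": int(len(windows)),
            "verdicts": verdicts.to_dict(orient="records"),
        }
        if outdir:
            windows.to_csv(outdir / "coverage_windows.tsv", sep="\t", index=False)

    if "popgen" in config.stages:
        stats = _popgen_stage(config, cohort)
        report["popgen"] = {"n_windows": int(len(stats))}
        if outdir:
            stats.to_csv(outdir / "window_stats.tsv", sep="\t", index=False)

    if "characterize" in config.stages:
        report["characterization"] = _characterize_stage(config, cohort)

    _consensus(config, evidence, roles, report)
    if outdir:
        (outdir / "par_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("running stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with the stage name
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("linkage")
def _linkage_stage(config: RunConfig, cohort, evidence: dict) -> tuple[lk.GeneticMap, dict]:
    gt, ped = cohort.genotypes, cohort.pedigree
    ts = lk.resolve_transmissions(gt, ped)
    markers = gt.markers
    filt = lk.filter_candidate_pseudoautosomal(gt, ped)
    retained = set(filt.loc[filt["retained"], "marker"])
    z_diff_markers = markers.loc[markers["role"] == ROLE_Z_DIFF, "marker"].tolist()
    anchors = z_diff_markers[: config.max_anchors]
    candidates = [m for m in markers.loc[markers["role"] != ROLE_Z_DIFF, "marker"] if m in retained]
    assignment = lk.assign_by_lod(gt, ped, candidates, anchors, config.lod_threshold, ts=ts)
    assigned = set(assignment.loc[assignment["assigned"], "marker"])

    z_order = markers[markers["chrom"] == "Z"].sort_values("chrom_pos")["marker"].tolist()
    map_markers = [m for m in z_order if m in assigned or m in z_diff_markers]
    gmap = lk.build_map(gt, ped, map_markers, config.map_function, ts=ts)
    boundary = lk.detect_par_boundary(gmap)

    meta = markers.set_index("marker")
    female_theta = dict(zip(gmap.table["marker"], gmap.table["theta_f"]))
    for scaffold in {s.name for s in config.sim.z_scaffold_order()}:
        scaf_markers = [m for m in map_markers if meta.at[m, "scaffold"] == scaffold]
        linked = [m for m in scaf_markers if m in assigned]
        rec = [
            m
            for m in scaf_markers
            if not np.isnan(female_theta.get(m, np.nan)) and female_theta[m] > 0
        ]
        evidence[scaffold]["linkage_assigned"] = bool(linked)
        evidence[scaffold]["female_recombination"] = bool(rec)
        evidence[scaffold]["n_markers_assigned"] = len(linked)
    # female heterozygosity evidence, per scaffold
    sex_of = dict(zip(ped.table["id"], ped.table["sex"]))
    females = [c for c in gt.calls.columns if sex_of.get(c) == "F"]
    for scaffold in evidence:
        calls = gt.calls.loc[markers.loc[markers["scaffold"] == scaffold, "marker"], females]
        het = calls.apply(lambda col: col.astype(str).str.len().eq(2) & (col.astype(str).str[0] != col.astype(str).str[1])).to_numpy()
        evidence[scaffold]["female_heterozygosity"] = bool(het.any())

    tables = {
        "n_candidates": int(len(candidates)),
        "n_assigned": int(len(assigned)),
        "boundary_marker": boundary.boundary_marker,
        "female_span_cm": boundary.female_span_cm,
        "male_map_length_cm": gmap.male_length(),
    }
    return gmap, tables


@_stage("coverage")
def _coverage_stage(config: RunConfig, cohort, evidence: dict):
    autosomes = [s.name for s in config.sim.scaffolds(ROLE_AUTOSOME)]
    lengths = {s.name: s.length for s in config.sim.genome_plan}
    windows, verdicts = cov.coverage_scan(
        cohort.depth, autosomes, config.window_size, config.coverage_tolerance, lengths
    )
    for _, row in verdicts.iterrows():
        if row["scaffold"] in evidence:
            evidence[row["scaffold"]]["coverage_verdict"] = row["verdict"]
    return windows, verdicts


@_stage("popgen")
def _popgen_stage(config: RunConfig, cohort) -> pd.DataFrame:
    lengths = {s.name: s.length for s in config.sim.z_scaffold_order()}
    return window_scan(
        cohort.haplotypes,
        lengths,
        window_sizes=config.popgen_window_sizes,
        focal_group={"species": "A"},
        species_pair=({"species": "A"}, {"species": "B"}),
        sex_pair=({"species": "A", "sex": "M"}, {"species": "A", "sex": "F"}),
        ld_max_dist=config.ld_max_dist,
        n_haplotypes_for_ld=2 * config.sim.n_haplotype_individuals,
    )


@_stage("characterize")
def _characterize_stage(config: RunConfig, cohort) -> dict:
    par_region = [(s.name, 0, s.length) for s in config.sim.scaffolds(ROLE_PAR)]
    par_len_padded = sum(s.length for s in config.sim.scaffolds(ROLE_PAR)) + config.gap_padding * (
        len(par_region) - 1
    )
    genes = gene_summary(cohort.annotation, par_region, region_length_bp=par_len_padded)
    comp = gc_repeat_windows(cohort.sequences, window_size=20_000)
    par_scafs = {s.name for s in config.sim.scaffolds(ROLE_PAR)}
    par_comp = comp[comp["scaffold"].isin(par_scafs)]
    tau = expression_tau(cohort.expression, cohort.expression_samples)
    mf = mf_expression_ratio(cohort.expression, cohort.expression_samples)
    gene_scaffold = cohort.annotation.loc[cohort.annotation["type"] == "gene"].set_index("feature_id")["scaffold"]
    par_genes = gene_scaffold[gene_scaffold.isin(par_scafs)].index
    return {
        "par_physical_length_bp": int(par_len_padded),
        "n_genes": genes.n_genes,
        "genes_per_mb": genes.genes_per_mb,
        "coding_fraction": genes.coding_fraction,
        "gc_mean": float(par_comp["gc_fraction"].mean()),
        "repeat_mean": float(par_comp["repeat_fraction"].mean()),
        "tau_par_mean": float(tau.loc[tau.index.isin(par_genes)].mean()),
        "mf_ratio_par_mean": float(mf.loc[mf.index.isin(par_genes), "mf_ratio"].mean()),
    }


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------


def _consensus(config: RunConfig, evidence: dict, roles: dict, report: dict) -> None:
    lengths = {s.name: s.length for s in config.sim.genome_plan}
    called = []
    for scaffold, ev in evidence.items():
        lines = {
            "linkage": ev.get("linkage_assigned", None) and ev.get("female_recombination", None),
            "coverage": (ev.get("coverage_verdict") == "PAR") if "coverage_verdict" in ev else None,
            "female_het": ev.get("female_heterozygosity", None),
        }
        available = {k: v for k, v in lines.items() if v is not None}
        if available and all(available.values()):
            verdict = "PAR"
            called.append(scaffold)
        elif available and not any(available.values()):
            verdict = "Z_diff"
        elif not available:
            verdict = "no-evidence"
        else:
            verdict = "conflicting"
        report["scaffolds"][scaffold] = {
            "true_role": roles[scaffold],
            "verdict": verdict,
            **{k: bool(v) if v is not None else None for k, v in lines.items()},
            "coverage_verdict": ev.get("coverage_verdict"),
        }
    par_len = (
        sum(lengths[s] for s in called) + config.gap_padding * (len(called) - 1) if called else 0
    )
    report["par_call"] = {
        "scaffolds": sorted(called),
        "physical_length_bp": int(par_len),
        "matches_truth": sorted(called) == sorted(s for s, r in roles.items() if r == ROLE_PAR),
    }


def save_config(config: RunConfig, path) -> None:
    data = asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
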