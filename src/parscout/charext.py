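"""Sequence composition, gene content and expression characterization.

Operates on a candidate region (e.g. a newly identified PAR) versus a
background (the rest of the chromosome): GC and softmask-repeat fractions in
windows, gene density and coding fraction, the tissue-specificity index tau,
male:female expression ratios, and a non-parametric bootstrap comparing a
region's statistic with a background window distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._util import tile_windows

GONADS_DEFAULT = ("testis", "ovary")


class UndefinedStatistic(ValueError):
    pass


# --------------------------------------------------------------------------
# composition windows
# --------------------------------------------------------------------------


def _get_sequences(fasta) -> dict[str, str]:
    if isinstance(fasta, dict):
        return fasta
    from pyfaidx import Fasta

    fa = Fasta(str(fasta))
    return {name: str(fa[name][:]) for name in fa.keys()}


def gc_repeat_windows(
    fasta,
    window_size: int = 20_000,
    windows: list[tuple[str, int, int]] | None = None,
    mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-window GC, repeat and N fractions from a softmasked FASTA.

    GC is computed over non-N bases (masked bases included); the repeat
    fraction is the softmasked (lowercase) share of the window, or the
    share covered by ``mask`` intervals (BED-like frame) when given.
    Windows extending beyond a scaffold end are truncated and flagged.
    """
    seqs = _get_sequences(fasta)
    if windows is None:
        windows = [
            (name, start, end)
            for name, seq in seqs.items()
            for start, end in tile_windows(len(seq), window_size)
        ]
    rows = []
    for scaffold, start, end in windows:
        seq = seqs[scaffold]
        truncated = end > len(seq)
        end_eff = min(end, len(seq))
        sub = seq[start:end_eff]
        n = len(sub)
        if n == 0:
            rows.append(dict(scaffold=scaffold, start=start, end=end_eff, gc_fraction=np.nan,
                             repeat_fraction=np.nan, n_fraction=np.nan, truncated=truncated))
            continue
        arr = np.frombuffer(sub.encode(), dtype=np.uint8)
        is_n = (arr == ord("N")) | (arr == ord("n"))
        gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8)).sum()
        non_n = n - int(is_n.sum())
        if mask is not None:
            repeat_bp = _masked_bp(mask, scaffold, start, end_eff)
        else:
            repeat_bp = int((arr >= ord("a")).sum())  # lowercase bases
        rows.append(
            dict(
                scaffold=scaffold,
                start=start,
                end=end_eff,
                gc_fraction=gc / non_n if non_n else np.nan,
                repeat_fraction=repeat_bp / n,
                n_fraction=is_n.sum() / n,
                truncated=truncated,
            )
        )
    return pd.DataFrame(rows)


def _masked_bp(mask: pd.DataFrame, scaffold: str, start: int, end: int) -> int:
    sub = mask[mask["scaffold"] == scaffold]
    total = 0
    for _, row in sub.iterrows():
        total += max(0, min(int(row["end"]), end) - max(int(row["start"]), start))
    return total


# --------------------------------------------------------------------------
# gene content
# --------------------------------------------------------------------------


@dataclass
class GeneSummary:
    region_bp: int
    n_genes: int
    coding_bp: int

    @property
    def genes_per_mb(self) -> float:
        return self.n_genes / (self.region_bp * 1e-6)

    @property
    def coding_fraction(self) -> float:
        return self.coding_bp / self.region_bp


def _gff_to_frame(gff) -> pd.DataFrame:
    """Accept the simulator's feature frame or a GFF3 file path (via gffutils)."""
    if isinstance(gff, pd.DataFrame):
        return gff
    import gffutils

    db = gffutils.create_db(str(gff), ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.all_features():
        rows.append(
            dict(
                scaffold=feat.seqid,
                type=feat.featuretype,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                feature_id=feat.id,
            )
        )
    return pd.DataFrame(rows)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered bp of 1-based inclusive intervals (overlaps collapsed)."""
    total = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end >= start:
            total += end - start + 1
            last_end = max(last_end, end)
    return total


def gene_summary(
    gff,
    region: list[tuple[str, int, int]],
    region_length_bp: int | None = None,
) -> GeneSummary:
    """Gene count, density and coding fraction for a region.

    ``region`` is a list of (scaffold, start, end) with 0-based half-open
    coordinates.  A gene belongs to the region iff its start coordinate
    falls inside (so boundary-straddling genes are counted exactly once);
    coding bp is the union of CDS intervals of any feature inside the
    region, clipped to it.  ``region_length_bp`` may override the physical
    length (e.g. to include inter-scaffold gap padding).
    """
    feats = _gff_to_frame(gff)
    length = region_length_bp if region_length_bp is not None else sum(e - s for _, s, e in region)
    if length <= 0:
        raise UndefinedStatistic("empty region")
    if feats.empty:
        return GeneSummary(region_bp=length, n_genes=0, coding_bp=0)
    genes = feats[feats["type"] == "gene"]
    n_genes = 0
    for _, g in genes.iterrows():
        start0 = int(g["start"]) - 1
        if any(g["scaffold"] == scaf and s <= start0 < e for scaf, s, e in region):
            n_genes += 1
    cds = feats[feats["type"] == "CDS"]
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for _, c in cds.iterrows():
        for scaf, s, e in region:
            if c["scaffold"] != scaf:
                continue
            clip_start = max(int(c["start"]), s + 1)  # 1-based
            clip_end = min(int(c["end"]), e)
            if clip_end >= clip_start:
                per_scaffold.setdefault(scaf, []).append((clip_start, clip_end))
    coding_bp = sum(_union_length(iv) for iv in per_scaffold.values())
    return GeneSummary(region_bp=length, n_genes=n_genes, coding_bp=coding_bp)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------


def tau_specificity(values, log_transform: bool = False) -> float:
    """Tissue-specificity index tau = sum_i (1 - x_i/x_max) / (N - 1).

    0 for uniform expression, 1 for single-tissue expression.  ``values``
    are per-tissue expression levels (>= 0); with ``log_transform`` they are
    log2(x+1)-transformed first.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise UndefinedStatistic("tau needs at least two tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    if x.max() == 0:
        raise UndefinedStatistic("tau undefined for an unexpressed gene")
    return float((1.0 - x / x.max()).sum() / (len(x) - 1))


def tissue_means(matrix: pd.DataFrame, samples: pd.DataFrame, sex: str | None = None) -> pd.DataFrame:
    """Gene x tissue mean expression, optionally restricted to one sex."""
    meta = samples if sex is None else samples[samples["sex"] == sex]
    cols = {}
    for tissue, grp in meta.groupby("tissue", sort=True):
        cols[tissue] = matrix[grp["sample"].tolist()].mean(axis=1)
    return pd.DataFrame(cols)


def expression_tau(matrix: pd.DataFrame, samples: pd.DataFrame, log_transform: bool = False) -> pd.Series:
    """Per-gene tau over tissue-mean expression (sexes pooled)."""
    means = tissue_means(matrix, samples)
    return means.apply(lambda row: tau_specificity(row.to_numpy(), log_transform), axis=1).rename("tau")


def mf_expression_ratio(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    exclude_tissues: tuple[str, ...] = GONADS_DEFAULT,
) -> pd.DataFrame:
    """Per-gene male:female expression ratio, averaged over shared tissues.

    For each tissue with samples of both sexes (gonads excluded by default),
    the ratio of male mean to female mean is computed; tissues where the
    female mean is zero are skipped for that gene.  ``mf_ratio`` is the mean
    ratio across usable tissues.
    """
    m = tissue_means(matrix, samples, "M")
    f = tissue_means(matrix, samples, "F")
    shared = [t for t in m.columns if t in f.columns and t not in exclude_tissues]
    if not shared:
        raise UndefinedStatistic("no shared non-excluded tissues")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = m[shared] / f[shared]
    ratios = ratios.replace([np.inf, -np.inf], np.nan)
    out = pd.DataFrame(
        {
            "mf_ratio": ratios.mean(axis=1, skipna=True),
            "n_tissues": ratios.notna().sum(axis=1),
        }
    )
    out.index.name = "gene"
    return out


def tissue_specific_calls(
    matrix: pd.DataFrame, samples: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Flag genes expressed (> threshold) in exactly one tissue; name it."""
    means = tissue_means(matrix, samples)
    expressed = means > threshold
    n = expressed.sum(axis=1)
    tissue = np.where(n == 1, expressed.idxmax(axis=1), "")
    return pd.DataFrame({"n_tissues_expressed": n, "specific": n == 1, "tissue": tissue})


def specificity_by_chance(n_genes: int, n_specific: int, background_freq: float) -> float:
    """P(at least ``n_specific`` of ``n_genes`` genes specific) under a binomial null."""
    if not 0 <= background_freq <= 1:
        raise ValueError("background frequency must be a probability")
    return float(binom.sf(n_specific - 1, n_genes, background_freq))


# --------------------------------------------------------------------------
# bootstrap comparison
# --------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    p_value: float  # (k + 1) / (B + 1)
    n_extreme: int
    n_resamples: int
    tail: str
    region_value: float

    @property
    def p_floor(self) -> float:
        return 1.0 / (self.n_resamples + 1)

    @property
    def display(self) -> str:
        if self.n_extreme == 0:
            return f"<{self.p_floor:.2g}"
        return f"{self.p_value:.4g}"


def bootstrap_window_test(
    background: np.ndarray | pd.Series,
    region_value: float,
    n_resamples: int = 10_000,
    tail: str = "two",
    block: int = 1,
    rng: np.random.Generator | int | None = None,
) -> BootstrapResult:
    """Empirical P for a region statistic against background windows.

    Each resample draws ``block`` contiguous background windows (with
    replacement of the starting window, wrapping at the end) and averages
    them, emulating a region assembled from same-size windows; ``block=1``
    is the plain case of one region-sized window.  The empirical P is
    (k+1)/(B+1) with k the number of resamples at least as extreme as the
    observed value under the chosen tail ('low', 'high' or 'two').
    """
    values = np.asarray(background, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise UndefinedStatistic("need at least two background windows")
    if n_resamples < 1:
        raise ValueError("need at least one resample")
    if tail not in ("low", "high", "two"):
        raise ValueError("tail must be 'low', 'high' or 'two'")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    starts = rng.integers(0, len(values), n_resamples)
    if block == 1:
        stats = values[starts]
    else:
        idx = (starts[:, None] + np.arange(block)[None, :]) % len(values)
        stats = values[idx].mean(axis=1)
    if tail == "high":
        k = int((stats >= region_value).sum())
    elif tail == "low":
        k = int((stats <= region_value).sum())
    else:
        center = np.median(stats)
        k = int((np.abs(stats - center) >= abs(region_value - center)).sum())
    return BootstrapResult(
        p_value=(k + 1) / (n_resamples + 1),
        n_extreme=k,
        n_resamples=n_resamples,
        tail=tail,
        region_value=float(region_value),
    )
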