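"""Sex-contrasted read-depth windows: PAR versus hemizygous-Z classification.

A region that recombines with the W in female meiosis is present in two
copies in both sexes, so pooled male and female sequencing show equal depth
there; the differentiated Z is single-copy in females and shows a twofold
male excess.  Windows are classified on the male:female depth ratio after
normalizing by the autosomal average ratio (which absorbs unequal total
sequencing effort between the sex pools).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LABEL_PAR = "PAR-like"
LABEL_HEMI = "hemizygous-Z"
LABEL_AMBIGUOUS = "ambiguous"

WINDOW_SIZE_DEFAULT = 200_000


def window_depth(
    depth: pd.DataFrame,
    window_size: int = WINDOW_SIZE_DEFAULT,
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate a per-base depth table into windows.

    Input columns: scaffold, pos (1-based), depth_M, depth_F (pooled).
    Output: one row per window with mean and median depth per sex; windows
    tile each scaffold; a final window shorter than ``window_size`` is kept
    and flagged ``short``.  Scaffolds listed in ``scaffold_lengths`` but
    absent from the table yield zero-depth windows.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    d = depth.copy()
    d["start"] = ((d["pos"] - 1) // window_size) * window_size
    grouped = d.groupby(["scaffold", "start"], sort=True).agg(
        mean_M=("depth_M", "mean"),
        median_M=("depth_M", "median"),
        mean_F=("depth_F", "mean"),
        median_F=("depth_F", "median"),
        n_bases=("pos", "size"),
        max_pos=("pos", "max"),
    )
    out = grouped.reset_index()
    out["end"] = out["start"] + np.minimum(window_size, out["max_pos"] - out["start"])
    out = out.drop(columns="max_pos")
    out["short"] = (out["end"] - out["start"]) < window_size
    if scaffold_lengths:
        rows = []
        seen = set(zip(out["scaffold"], out["start"]))
        for scaffold, length in scaffold_lengths.items():
            for start in range(0, length, window_size):
                if (scaffold, start) not in seen:
                    end = min(start + window_size, length)
                    rows.append(
                        dict(scaffold=scaffold, start=start, end=end, mean_M=0.0, median_M=0.0,
                             mean_F=0.0, median_F=0.0, n_bases=0, short=end - start < window_size)
                    )
        if rows:
            out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
            out = out.sort_values(["scaffold", "start"]).reset_index(drop=True)
    return out


def normalize_mf(
    windows: pd.DataFrame, autosomal_scaffolds: set[str] | list[str], use: str = "mean"
) -> pd.DataFrame:
    """Add raw and autosome-normalized M/F ratios.

    The raw ratio uses window ``mean`` depths by default (``median``
    optional); the normalizer is the average raw ratio over autosomal
    windows with nonzero female depth, so autosomal windows have mean
    normalized ratio 1 by construction.
    """
    if use not in ("mean", "median"):
        raise ValueError("use must be 'mean' or 'median'")
    out = windows.copy()
    male, female = out[f"{use}_M"], out[f"{use}_F"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_raw"] = np.where(female > 0, male / female, np.nan)
    auto = out["scaffold"].isin(set(autosomal_scaffolds)) & out["ratio_raw"].notna()
    if not auto.any():
        raise ValueError("no autosomal window with nonzero female depth")
    norm = out.loc[auto, "ratio_raw"].mean()
    out["ratio_norm"] = out["ratio_raw"] / norm
    return out


def classify_windows(windows: pd.DataFrame, tolerance: float = 0.25) -> pd.DataFrame:
    """Label windows by log2 normalized ratio.

    PAR-like when |log2 r| <= tolerance, hemizygous-Z when
    |log2 r - 1| <= tolerance, else ambiguous.  Undefined ratios (zero
    female depth) are ambiguous and excluded from scaffold verdicts.
    """
    out = windows.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(out["ratio_norm"])
    label = np.full(len(out), LABEL_AMBIGUOUS, dtype=object)
    label[np.abs(log2r) <= tolerance] = LABEL_PAR
    label[np.abs(log2r - 1.0) <= tolerance] = LABEL_HEMI
    label[~np.isfinite(log2r)] = LABEL_AMBIGUOUS
    out["log2_ratio"] = log2r
    out["label"] = label
    return out


def classify_scaffolds(windows: pd.DataFrame, min_window_fraction: float = 0.5) -> pd.DataFrame:
    """Majority vote over each scaffold's informative (non-ambiguous) windows.

    Short terminal windows below ``min_window_fraction`` of the modal window
    span are excluded — unless a scaffold is shorter than a window, in which
    case its short window is all the evidence there is and is used.  Ties
    and all-ambiguous scaffolds yield an ambiguous verdict.  ``fraction`` is
    the winning share of informative windows.
    """
    rows = []
    spans = windows["end"] - windows["start"]
    full = spans.max() if len(spans) else 0
    eligible = windows[spans >= min_window_fraction * full]
    only_short = set(windows["scaffold"]) - set(eligible["scaffold"])
    eligible = pd.concat([eligible, windows[windows["scaffold"].isin(only_short)]])
    for scaffold, grp in eligible.groupby("scaffold", sort=True):
        informative = grp[grp["label"] != LABEL_AMBIGUOUS]
        n_par = int((informative["label"] == LABEL_PAR).sum())
        n_hemi = int((informative["label"] == LABEL_HEMI).sum())
        if n_par + n_hemi == 0 or n_par == n_hemi:
            verdict, fraction = LABEL_AMBIGUOUS, np.nan
        elif n_par > n_hemi:
            verdict, fraction = "PAR", n_par / (n_par + n_hemi)
        else:
            verdict, fraction = "hemizygous-Z", n_hemi / (n_par + n_hemi)
        rows.append(
            {
                "scaffold": scaffold,
                "verdict": verdict,
                "fraction": fraction,
                "n_windows": len(grp),
                "n_informative": n_par + n_hemi,
            }
        )
    return pd.DataFrame(rows)


def coverage_scan(
    depth: pd.DataFrame,
    autosomal_scaffolds: set[str] | list[str],
    window_size: int = WINDOW_SIZE_DEFAULT,
    tolerance: float = 0.25,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: windows -> normalized ratios -> labels -> scaffold verdicts."""
    w = window_depth(depth, window_size, scaffold_lengths)
    w = normalize_mf(w, autosomal_scaffolds)
    w = classify_windows(w, tolerance)
    return w, classify_scaffolds(w)


def plot_ratio_track(windows: pd.DataFrame, path, scaffold_order: list[str] | None = None) -> None:
    """Normalized M/F ratio per window along concatenated scaffolds (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = windows.copy()
    if scaffold_order:
        w["scaffold"] = pd.Categorical(w["scaffold"], scaffold_order, ordered=True)
        w = w.sort_values(["scaffold", "start"])
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.scatter(range(len(w)), w["ratio_norm"], s=8, c=(w["label"] == LABEL_PAR).map({True: "tab:blue", False: "tab:red"}))
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.axhline(2.0, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("window index")
    ax.set_ylabel("normalized M/F depth ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
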