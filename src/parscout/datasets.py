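"""Bundled reference data: the collared flycatcher distal-Z genetic map.

The map covers the 1.5 Mb distal tip of the Z chromosome: the three
pseudoautosomal scaffolds (N00298, N00378, N02597; 436.0, 182.2 and 2.3 kb)
followed by differentiated-Z scaffolds.  Cumulative female positions stop
increasing at N02597:626 — the PAR boundary — while the male map keeps
extending, the signature this package's boundary detector looks for.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .linkage import GeneticMap

PAR_SCAFFOLDS = ("N00298", "N00378", "N02597")
GAP_PADDING_BP = 5_000


def _data_path(name: str):
    return resources.files("parscout.data").joinpath(name)


def distal_z_map() -> GeneticMap:
    """The published-style distal-Z best-order map as a GeneticMap."""
    with _data_path("distal_z_map.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return GeneticMap.from_positions(table)


def distal_z_scaffolds() -> pd.DataFrame:
    """Scaffold order, roles and known lengths of the distal Z."""
    with _data_path("distal_z_scaffolds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def scaffold_lengths() -> dict[str, int]:
    """Known scaffold lengths in bp (scaffolds of unknown length omitted)."""
    df = distal_z_scaffolds()
    known = df.dropna(subset=["length"])
    return {row["scaffold"]: int(row["length"]) for _, row in known.iterrows()}


def scaffold_order() -> list[str]:
    return distal_z_scaffolds()["scaffold"].tolist()
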