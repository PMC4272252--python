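"""Small shared helpers: seeding, window arithmetic, marker ids."""

from __future__ import annotations

import numpy as np

#: order in which the simulator stages draw their child seeds; fixed so that a
#: given master seed always yields the same streams regardless of call order.
_STAGE_STREAMS = (
    "pedigree",
    "genotypes",
    "depth",
    "haplotypes",
    "sequences",
    "expression",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return an independent, reproducible generator for a named stage.

    All randomness in the package flows through here so that a single integer
    seed makes every output byte-identical across runs.
    """
    if stage not in _STAGE_STREAMS:
        raise ValueError(f"unknown rng stage {stage!r}")
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_STREAMS))
    return np.random.default_rng(children[_STAGE_STREAMS.index(stage)])


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Split a ``scaffold:position`` marker id into its parts (1-based bp)."""
    scaffold, _, pos = marker_id.rpartition(":")
    if not scaffold or not pos.isdigit():
        raise ValueError(f"marker id {marker_id!r} is not 'scaffold:position'")
    position = int(pos)
    if position < 1:
        raise ValueError(f"marker position must be >= 1, got {position}")
    return scaffold, position


def marker_id(scaffold: str, position: int) -> str:
    return f"{scaffold}:{position}"


def tile_windows(length: int, size: int) -> list[tuple[int, int]]:
    """0-based half-open windows tiling [0, length); the last one may be short."""
    if size <= 0:
        raise ValueError("window size must be positive")
    return [(s, min(s + size, length)) for s in range(0, length, size)]
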