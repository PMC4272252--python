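"""Multi-generation pedigree simulation.

Families follow a line-breeding design: a founder couple, then in each later
generation one offspring of the previous mating paired with an unrelated
immigrant.  Every non-founder has exactly one sire and one dam recorded, so
each offspring genotype corresponds to one male and one female meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

PEDIGREE_COLUMNS = ("id", "family", "sire", "dam", "sex", "generation")
MISSING_PARENT = "0"


@dataclass
class Pedigree:
    """Individuals with sex and parent links (``sire``/``dam`` = '0' for founders)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PEDIGREE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def sex_of(self, individual: str) -> str:
        return self._row(individual)["sex"]

    def parents_of(self, individual: str) -> tuple[str, str] | None:
        """(sire, dam) of a non-founder, or None for founders."""
        row = self._row(individual)
        if row["sire"] == MISSING_PARENT or row["dam"] == MISSING_PARENT:
            return None
        return row["sire"], row["dam"]

    def _row(self, individual: str) -> pd.Series:
        rows = self.table[self.table["id"] == individual]
        if rows.empty:
            raise KeyError(f"unknown individual {individual!r}")
        return rows.iloc[0]

    def trios(self) -> pd.DataFrame:
        """All (child, sire, dam) rows where both parents are recorded."""
        t = self.table
        return t[(t["sire"] != MISSING_PARENT) & (t["dam"] != MISSING_PARENT)][
            ["id", "sire", "dam", "sex"]
        ].rename(columns={"id": "child"})

    def n_meioses(self) -> int:
        """Meioses per sex represented in the pedigree (= number of trios)."""
        return len(self.trios())

    def validate(self) -> None:
        """Referential integrity: every named parent is in the table, sexes match."""
        known = dict(zip(self.table["id"], self.table["sex"]))
        for _, row in self.trios().iterrows():
            for parent, expected in ((row["sire"], "M"), (row["dam"], "F")):
                if parent not in known:
                    raise ValueError(f"parent {parent!r} of {row['child']!r} not in pedigree")
                if known[parent] != expected:
                    raise ValueError(f"parent {parent!r} has sex {known[parent]}, expected {expected}")


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Simulate ``n_families`` line-bred families over ``n_generations``.

    Offspring sexes are drawn at random except that the first offspring of each
    non-terminal mating is forced to the sex needed to continue the line
    (alternating, so both male and female meioses accumulate).
    """
    if config.n_families < 1 or config.offspring_per_family < 1:
        raise ConfigError("n_families and offspring_per_family must be >= 1")
    if rng is None:
        from .._util import stage_rng

        rng = stage_rng(config.seed, "pedigree")

    records: list[dict] = []
    for fam_idx in range(config.n_families):
        fam = f"fam{fam_idx + 1:02d}"
        sire = f"{fam}_g1_sire"
        dam = f"{fam}_g1_dam"
        records.append(dict(id=sire, family=fam, sire=MISSING_PARENT, dam=MISSING_PARENT, sex="M", generation=1))
        records.append(dict(id=dam, family=fam, sire=MISSING_PARENT, dam=MISSING_PARENT, sex="F", generation=1))
        for gen in range(2, config.n_generations + 1):
            terminal = gen == config.n_generations
            # alternate the sex of the line-continuing child between generations
            line_sex = "F" if gen % 2 == 0 else "M"
            next_sire = next_dam = None
            for k in range(config.offspring_per_family):
                child = f"{fam}_g{gen}_o{k + 1}"
                if k == 0 and not terminal:
                    sex = line_sex
                else:
                    sex = "F" if rng.random() < 0.5 else "M"
                records.append(dict(id=child, family=fam, sire=sire, dam=dam, sex=sex, generation=gen))
                if k == 0 and not terminal:
                    if sex == "F":
                        next_dam = child
                    else:
                        next_sire = child
            if not terminal:
                mate = f"{fam}_g{gen}_mate"
                mate_sex = "M" if line_sex == "F" else "F"
                records.append(
                    dict(id=mate, family=fam, sire=MISSING_PARENT, dam=MISSING_PARENT, sex=mate_sex, generation=gen)
                )
                sire = next_sire if next_sire is not None else mate
                dam = next_dam if next_dam is not None else mate
    ped = Pedigree(pd.DataFrame.from_records(records, columns=list(PEDIGREE_COLUMNS)))
    ped.validate()
    return ped


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str}))
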