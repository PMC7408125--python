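"""Compound records and the packaged bagremycin/bagrelactone table.

The packaged table transcribes the 33 bagremycin- and bagrelactone-related
ions characterised across the *Streptomyces lunaelactis* strain collection:
printed elemental formula, experimental m/z, mass deviation (ppm), the set
of producing strains (best producer flagged), diagnostic-fragment group
(1 = classical bagremycins, 2 = sulfur-bearing bagremycins, 3 =
bagrelactones, ND = not determined) and whether the compound was previously
known.

Published natural-product tables mix two ion-formula conventions — some
rows write the cation composition outright, others write the neutral
molecule whose [M+H]+ is observed.  The loader resolves the convention per
row by testing which one reproduces the printed m/z within 1 ppm; rows
reproducible under neither are flagged ``inconsistent`` and carry no
reading, so downstream mass arithmetic can exclude them explicitly instead
of silently propagating a typo.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .formula import Formula, IonReading, ion_mz, resolve_reading

__all__ = ["CompoundRecord", "load_compound_table"]


@dataclass(frozen=True)
class CompoundRecord:
    """One named (or formula-only) compound and who produces it."""

    name: str
    formula: Formula
    reading: IonReading | None  # None when the printed formula/m-z pair is inconsistent
    mz: float                   # experimental ion m/z as printed
    dm_ppm: float               # printed mass deviation
    group: str                  # "1", "2", "3" or "ND"
    neutral_loss: bool          # diagnostic tag seen as a neutral loss
    alt_tag: bool               # unsaturated-form alternative tag observed
    producing_strains: frozenset[str]
    best_producers: tuple[str, ...]
    known: bool                 # previously reported compound

    @property
    def inconsistent(self) -> bool:
        return self.reading is None

    @property
    def named(self) -> bool:
        return bool(self.name)

    def theoretical_mz(self) -> float:
        if self.reading is None:
            raise ValueError(f"{self.name or self.formula}: printed formula/m-z pair is inconsistent")
        return ion_mz(self.formula, self.reading)


def load_compound_table() -> list[CompoundRecord]:
    """Load the packaged 33-compound table as :class:`CompoundRecord` objects."""
    with resources.files("strainscope").joinpath("data/compound_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        f = Formula.parse(row["formula"])
        mz = float(row["mz_exp"])
        records.append(
            CompoundRecord(
                name=row["name"],
                formula=f,
                reading=resolve_reading(f, mz, tol_ppm=1.0),
                mz=mz,
                dm_ppm=float(row["dm_ppm"]),
                group=row["group"],
                neutral_loss=row["nl"] == "1",
                alt_tag=row["alt_tag"] == "1",
                producing_strains=frozenset(row["producers"].split(",")),
                best_producers=tuple(row["best"].split("|")),
                known=row["known"] == "1",
            )
        )
    return records
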