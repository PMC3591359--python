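"""Phenotype table container and the log10 transform.

Five traits are carried per individual: larval, pupal and total development
time (LDT, PDT, TDT, days), adult body mass (Mb, mg) and routine metabolic
rate (RMR, µL CO₂ h⁻¹), together with the design factors population,
replicate line (nested in population), ethanol environment, sex, metabolic
chamber and record hour.  All downstream genetic analyses operate on the
log10 scale to remove mean–variance scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

TRAITS = ("ldt", "pdt", "tdt", "mb", "rmr")
FACTORS = ("population", "line", "ethanol", "sex", "chamber", "hour")
COLUMNS = ("id",) + FACTORS + TRAITS

#: a development check every 24 h allows this much slack in TDT = LDT + PDT
TDT_TOLERANCE_DAYS = 1.0


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Per-individual trait values plus design factors.

    ``scale`` is ``"raw"`` (days / mg / µL CO₂ h⁻¹) or ``"log10"``.
    Missing trait cells are NaN; factor cells may be empty strings for
    factors that do not apply (e.g. chamber for unmeasured flies).
    """

    df: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise PhenotypeError(f"phenotype table missing columns {missing}")
        if self.scale not in ("raw", "log10"):
            raise PhenotypeError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            self._check_tdt()

    def _check_tdt(self):
        d = self.df
        ok = d[["ldt", "pdt", "tdt"]].notna().all(axis=1)
        if ok.any():
            gap = (d.loc[ok, "tdt"] - d.loc[ok, "ldt"] - d.loc[ok, "pdt"]).abs()
            bad = d.loc[ok].loc[gap > TDT_TOLERANCE_DAYS, "id"]
            if len(bad):
                warnings.warn(
                    f"TDT != LDT + PDT beyond {TDT_TOLERANCE_DAYS} day for "
                    f"{len(bad)} individuals (e.g. {bad.iloc[0]!r})",
                    stacklevel=3,
                )

    def __len__(self):
        return len(self.df)

    def validate_against(self, ped: Pedigree) -> None:
        unknown = [i for i in self.df["id"] if i not in ped]
        if unknown:
            raise PhenotypeError(
                f"{len(unknown)} individuals not in pedigree (e.g. {unknown[0]!r})"
            )


def log10_transform(tab: PhenotypeTable) -> PhenotypeTable:
    """Return a log10-scaled copy of a raw table.

    Raises on non-positive trait values (listing offending ids) and on an
    already-transformed table, so the transform cannot be applied twice.
    """
    if tab.scale == "log10":
        raise PhenotypeError("table is already log10-transformed")
    df = tab.df.copy()
    for t in TRAITS:
        vals = df[t]
        bad = df.loc[vals.notna() & (vals <= 0), "id"].tolist()
        if bad:
            raise PhenotypeError(
                f"non-positive values of {t!r} for ids {bad[:5]}"
                + ("..." if len(bad) > 5 else "")
            )
    for t in TRAITS:
        df[t] = np.log10(df[t])
    return PhenotypeTable(df=df, scale="log10")


def read_phenotypes(path, scale: str = "raw") -> PhenotypeTable:
    """Read a phenotype CSV (columns id,population,line,ethanol,sex,chamber,hour,ldt,pdt,tdt,mb,rmr)."""
    df = pd.read_csv(path, dtype={c: str for c in ("id",) + FACTORS})
    for f in ("id",) + FACTORS:
        if f in df.columns:
            df[f] = df[f].fillna("")
    return PhenotypeTable(df=df[list(COLUMNS)], scale=scale)


def write_phenotypes(tab: PhenotypeTable, path) -> None:
    tab.df.to_csv(path, index=False)
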