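"""Plain-text readers and writers for every pipeline artifact.

All formats are whitespace- or comma-delimited text with headers, so
outputs are diffable and bit-stable under a fixed seed:

* point clouds: ``x,y,z,return_number,classification`` (classification
  2 = ground, 1 = vegetation — the LAS class vocabulary);
* stem tables: ``plot_id,x,y,dbh_cm,height_m,pft``;
* canopy profiles: ``column_id,z_mid,lad``;
* climate series: ``year,month,precip_mm,pet_mm[,response...]``;
* patch ("pss") and cohort ("css") initial-condition files in the
  whitespace-delimited dialect ecosystem-demography models ingest.

The pss columns are ``time patch trk age area water fsc stsc stsl ssc
lai msn fsn``: trk is the land-use track, area the patch weight within
its group, and fsc/stsc/stsl/ssc the fast/structural soil and surface
necromass carbon pools, which are filled from configurable defaults
because initial necromass stocks are uncertain.  The css columns are
``time patch cohort dbh hite pft n bdead balive lai`` with n in stems
m^-2.  Writers use fixed decimal formatting so write -> read -> write
round trips are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .allometry import Cohort, CohortStack

__all__ = [
    "write_point_cloud_text", "read_point_cloud_text",
    "write_stem_table", "read_stem_table",
    "write_profiles", "read_profiles",
    "write_climate", "read_climate",
    "NecromassDefaults", "write_pss", "read_pss",
    "write_css", "read_css",
]


def write_point_cloud_text(cloud: pd.DataFrame, path) -> None:
    out = cloud.copy()
    out["classification"] = out.pop("is_ground").map({True: 2, False: 1})
    out.to_csv(path, index=False, float_format="%.4f",
               columns=["x", "y", "z", "return_number", "classification"])


def read_point_cloud_text(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_ground"] = df.pop("classification") == 2
    return df


def write_stem_table(stems: pd.DataFrame, path, plot_id: str = "plot") -> None:
    out = stems.copy()
    out.insert(0, "plot_id", plot_id)
    out.to_csv(path, index=False, float_format="%.4f",
               columns=["plot_id", "x", "y", "dbh_cm", "height_m", "pft"])


def read_stem_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles(profiles: list, path) -> None:
    """``column_id,z_mid,lad`` rows for one or many canopy profiles."""
    rows = []
    for prof in profiles:
        for z, lad in zip(prof.z_mid, prof.lad):
            rows.append({"column_id": prof.column_id, "z_mid": z, "lad": lad})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_climate(clim: pd.DataFrame, path) -> None:
    clim.to_csv(path, index=False, float_format="%.4f")


def read_climate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("precip_mm", "pet_mm"):
        if col not in df.columns:
            raise ValueError(f"climate file lacks required column {col!r}")
    return df


@dataclass(frozen=True)
class NecromassDefaults:
    """Initial necromass/soil pools for pss rows (kgC m^-2), configurable."""

    fsc: float = 0.15    # fast soil carbon
    stsc: float = 4.0    # structural soil carbon (incl. woody debris)
    stsl: float = 4.0    # structural soil lignin
    ssc: float = 5.0     # slow soil carbon
    water: float = 0.5   # relative soil-water content
    msn: float = 10.0    # mineralized soil nitrogen
    fsn: float = 1.0     # fast soil nitrogen


_PSS_COLS = ["time", "patch", "trk", "age", "area", "water", "fsc", "stsc",
             "stsl", "ssc", "lai", "msn", "fsn"]
_CSS_COLS = ["time", "patch", "cohort", "dbh", "hite", "pft", "n", "bdead",
             "balive", "lai"]


def write_pss(ensembles: list, path, time: float = 2016.0,
              age: float = 50.0,
              necromass: NecromassDefaults = NecromassDefaults()) -> None:
    """Write patch rows: one patch per ensemble member, weight 1/N."""
    lines = [" ".join(_PSS_COLS)]
    for ens in ensembles:
        n = len(ens.members)
        for stack in ens.members:
            row = [f"{time:.6f}", stack.column_id or "p0", "1",
                   f"{age:.6f}", f"{1.0 / n:.6f}",
                   f"{necromass.water:.6f}", f"{necromass.fsc:.6f}",
                   f"{necromass.stsc:.6f}", f"{necromass.stsl:.6f}",
                   f"{necromass.ssc:.6f}", f"{stack.lai:.6f}",
                   f"{necromass.msn:.6f}", f"{necromass.fsn:.6f}"]
            lines.append(" ".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    if list(df.columns) != _PSS_COLS:
        raise ValueError(f"unexpected pss header: {list(df.columns)}")
    return df


def write_css(ensembles: list, path, time: float = 2016.0,
              agb_fraction_dead: float = 0.7) -> None:
    """Write cohort rows for every patch in every ensemble.

    bdead/balive split total aboveground biomass per individual with a
    configurable structural fraction (the host model re-derives its own
    pools from DBH anyway).
    """
    from .allometry import agb_kg, default_allometry

    allom = default_allometry()
    lines = [" ".join(_CSS_COLS)]
    for ens in ensembles:
        for stack in ens.members:
            pid = stack.column_id or "p0"
            for ci, c in enumerate(stack):
                agb = agb_kg(c.dbh, c.pft, allom)
                row = [f"{time:.6f}", pid, f"{pid}_c{ci}",
                       f"{c.dbh:.6f}", f"{c.height:.6f}", c.pft,
                       f"{c.density:.8f}",
                       f"{agb * agb_fraction_dead:.6f}",
                       f"{agb * (1 - agb_fraction_dead):.6f}",
                       f"{c.lai:.6f}"]
                lines.append(" ".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_css(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    if list(df.columns) != _CSS_COLS:
        raise ValueError(f"unexpected css header: {list(df.columns)}")
    return df


def stacks_from_css(df: pd.DataFrame) -> list[CohortStack]:
    """Rebuild cohort stacks from a css table (round-trip support)."""
    stacks = []
    for pid, grp in df.groupby("patch", sort=True):
        cohorts = [
            Cohort(dbh=r.dbh, height=r.hite, pft=r.pft, density=r.n,
                   lai=r.lai)
            for r in grp.itertuples()
        ]
        stacks.append(CohortStack(cohorts, column_id=str(pid)))
    return stacks
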