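"""Trait tables, habitat classification, realm assignment, clade selection.

Species enter the analysis through three tables:

* a trait table (``species, height, fruit_diameter``) — maximum stem height
  in metres and fruit diameter in the source units; both are log10-transformed
  before any model fitting;
* an occurrence table (``species, unit, unit_class``) mapping species to
  geographic recording units tagged ``mainland`` / ``continental_island`` /
  ``volcanic_island``;
* a unit -> realm map assigning each unit to one of three biogeographical
  realms (Afrotropics, Australasia/IndoMalaya, Neotropics), with Hawaii
  routed to the Neotropics (its native palm lineage is of Neotropical
  ancestry, so the Hawaiian flora is analyzed with that realm).

A species recorded in more than one habitat category is *widespread* and is
excluded from the main analyses (but retained inside clades for model
fitting).  Widespread status is computed both globally and within each realm
separately: a species can be single-habitat within its realm yet widespread
globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from islandtraits.errors import DataError
from islandtraits.phylo import Phylogeny, normalize_label

__all__ = [
    "HABITATS",
    "REALMS",
    "TraitTable",
    "CladeSpec",
    "load_traits",
    "classify_habitat",
    "assign_realm",
    "select_clades",
    "match_tree_traits",
]

logger = logging.getLogger(__name__)

HABITATS = ("mainland", "continental_island", "volcanic_island")
REALMS = ("Afrotropics", "Australasia/IndoMalaya", "Neotropics")
WIDESPREAD = "widespread"


@dataclass
class TraitTable:
    """Species-level trait values with raw-unit provenance.

    ``data`` has one row per species with columns ``species``, the raw trait
    columns found in the source, and ``log_<trait>`` columns (log10) populated
    only where the raw value is strictly positive.  ``excluded`` reports the
    (species, column, reason) triples dropped from the log columns.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)
    excluded: pd.DataFrame = None

    def trait(self, column: str) -> dict:
        """Mapping species -> value for one column, NaNs dropped."""
        sub = self.data[["species", column]].dropna()
        return dict(zip(sub["species"], sub[column].astype(float)))


def load_traits(csv_path, transform: bool = True,
                trait_columns=("height", "fruit_diameter"),
                units=None) -> TraitTable:
    """Load a trait CSV and add log10 columns.

    Raw values must be strictly positive to enter a log column; non-positive
    or missing values are excluded from that column and listed in the
    exclusion report (they are never zero-filled).
    """
    df = pd.read_csv(csv_path)
    if "species" not in df.columns:
        raise DataError("trait CSV must have a 'species' column")
    df["species"] = df["species"].astype(str).map(normalize_label)
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate species in trait table: {sorted(set(dup))}")
    excluded = []
    for col in trait_columns:
        if col not in df.columns:
            continue
        raw = pd.to_numeric(df[col], errors="coerce")
        bad_parse = df[col].notna() & raw.isna()
        if bad_parse.any():
            rows = df.index[bad_parse].tolist()
            raise DataError(f"unparseable numeric in column {col!r}, rows {rows}")
        df[col] = raw
        if transform:
            ok = raw > 0
            log = pd.Series(np.nan, index=df.index)
            log[ok] = np.log10(raw[ok])
            df[f"log_{col}"] = log
            for i in df.index[~ok & df[col].notna()]:
                excluded.append((df.at[i, "species"], col, "non-positive value"))
            for i in df.index[df[col].isna()]:
                excluded.append((df.at[i, "species"], col, "missing value"))
    report = pd.DataFrame(excluded, columns=["species", "column", "reason"])
    if len(report):
        logger.warning("excluded %d species/column pairs from log transform",
                       len(report))
    return TraitTable(data=df, units=units or {}, excluded=report)


# ---------------------------------------------------------------------------
# habitat / realm classification


def _as_records(records) -> pd.DataFrame:
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    need = {"species", "unit", "unit_class"}
    if not need <= set(df.columns):
        raise DataError(f"occurrence table needs columns {sorted(need)}")
    bad = set(df["unit_class"]) - set(HABITATS)
    if bad:
        raise DataError(f"unknown unit_class values: {sorted(bad)}")
    df["species"] = df["species"].astype(str).map(normalize_label)
    return df


def assign_realm(records, realm_map: dict) -> pd.DataFrame:
    """Per-species realm from the unit -> realm map.

    Species whose units span several realms are flagged (``realm`` NaN,
    ``realm_conflict`` True) and are excluded from realm-level analyses.
    The Hawaii -> Neotropics override is an ordinary entry of ``realm_map``.
    """
    df = _as_records(records)
    missing = sorted(set(df["unit"]) - set(realm_map))
    if missing:
        raise DataError(f"units absent from realm map: {missing}")
    df["realm"] = df["unit"].map(realm_map)
    bad_realm = sorted(set(df["realm"]) - set(REALMS))
    if bad_realm:
        raise DataError(f"realm map contains unknown realms: {bad_realm}")
    out = []
    for sp, grp in df.groupby("species", sort=True):
        realms = sorted(set(grp["realm"]))
        out.append({
            "species": sp,
            "realm": realms[0] if len(realms) == 1 else np.nan,
            "realm_conflict": len(realms) > 1,
        })
    return pd.DataFrame(out)


def classify_habitat(records, realm_map: dict) -> pd.DataFrame:
    """Classify each species as mainland / continental_island /
    volcanic_island / widespread, globally and within its realm.

    Returns one row per species with columns ``species, habitat, realm,
    realm_habitat, realm_conflict``: ``habitat`` is the global
    classification (``widespread`` when records span more than one of the
    three categories), ``realm_habitat`` the same computed from the species'
    records within its own realm only.  Classification depends only on the
    *set* of (unit, class) records, so it is idempotent and independent of
    row order.
    """
    df = _as_records(records)
    realms = assign_realm(df, realm_map).set_index("species")
    df["realm"] = df["unit"].map(realm_map)
    rows = []
    for sp, grp in df.groupby("species", sort=True):
        cats = set(grp["unit_class"])
        habitat = cats.pop() if len(cats) == 1 else WIDESPREAD
        realm = realms.at[sp, "realm"]
        conflict = bool(realms.at[sp, "realm_conflict"])
        if conflict or pd.isna(realm):
            realm_habitat = np.nan
        else:
            rcats = set(grp.loc[grp["realm"] == realm, "unit_class"])
            realm_habitat = rcats.pop() if len(rcats) == 1 else WIDESPREAD
        rows.append({
            "species": sp,
            "habitat": habitat,
            "realm": realm,
            "realm_habitat": realm_habitat,
            "realm_conflict": conflict,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tree/table matching and clade selection


def match_tree_traits(tree: Phylogeny, species) -> dict:
    """Report the overlap between tree tips and a species list.

    Matching uses the shared normalization (underscore = space); unmatched
    names are listed, never fuzzy-matched.
    """
    tipset = {normalize_label(l) for l in tree.tip_labels}
    spset = {normalize_label(str(s)) for s in species}
    matched = tipset & spset
    report = {
        "n_tree": len(tipset),
        "n_species": len(spset),
        "n_matched": len(matched),
        "tree_only": sorted(tipset - spset),
        "species_only": sorted(spset - tipset),
    }
    logger.info("matched %d/%d tree tips to the species table",
                len(matched), len(tipset))
    return report


@dataclass(frozen=True)
class CladeSpec:
    """A named candidate clade for per-habitat model fitting."""

    name: str
    taxa: frozenset
    habitat_label: str
    n_height: int
    n_fruit: int
    use_height: bool
    use_fruit: bool


def select_clades(tree: Phylogeny, traits: TraitTable, clade_taxa: dict,
                  clade_habitats: dict = None, min_n: int = 10,
                  height_col: str = "log_height",
                  fruit_col: str = "log_fruit_diameter"):
    """Screen named candidate clades for sufficient trait coverage.

    ``clade_taxa`` maps clade name -> iterable of taxon labels; a clade is
    usable for a trait only when at least ``min_n`` member species have data
    for it (clades failing for a trait stay listed with the use flag off).
    All member species are retained, including widespread ones — habitat
    filtering does not apply inside clades.
    """
    tipset = {normalize_label(l) for l in tree.tip_labels}
    height = {normalize_label(k) for k in traits.trait(height_col)} \
        if height_col in traits.data.columns else set()
    fruit = {normalize_label(k) for k in traits.trait(fruit_col)} \
        if fruit_col in traits.data.columns else set()
    out = []
    for name, taxa in clade_taxa.items():
        taxa_n = {normalize_label(str(t)) for t in taxa}
        missing = sorted(taxa_n - tipset)
        if missing:
            raise DataError(f"clade {name!r}: taxa absent from tree: {missing}")
        nh, nf = len(taxa_n & height), len(taxa_n & fruit)
        out.append(CladeSpec(
            name=name,
            taxa=frozenset(taxa_n),
            habitat_label=(clade_habitats or {}).get(name, ""),
            n_height=nh,
            n_fruit=nf,
            use_height=nh >= min_n,
            use_fruit=nf >= min_n,
        ))
    return out
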