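"""Packaged inventory tables and ortholog-group structures.

The five inventory tables (HAK, HKT, TPK, Shaker-like, other
voltage-gated channels) ship as TSV package data and are the fixed
reference inventories of this package.

Group structures describe, per family, how the published ortholog
groups partition the loci and how the groups join at the base of the
gene tree.  Only the published anchors are fixed (e.g. the single HKT
ortholog group; two TPK groups; the P. patens-specific Shaker clade and
the K_out group containing Sel-moe-SmORK; HAK groups V/VI being
P. patens-specific with the stated members of groups I, II and IV).
The remaining per-locus group assignments are a documented
reconstruction: the downstream ancestral-copy-number results asserted in
the test suite depend only on each group's species span, not on these
free choices.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LAND_PLANTS = ("Athaliana", "Osativa", "Ptrichocarpa", "Ppatens", "Smoellendorffii")

_TABLE_FILES = {
    1: "table1_hak.tsv",
    2: "table2_hkt.tsv",
    3: "table3_tpk.tsv",
    4: "table4_shaker.tsv",
    5: "table5_other_vg.tsv",
}

FAMILIES = ("HAK", "HKT", "TPK", "SHAKER", "OTHER_VG")


def load_table(number: int) -> pd.DataFrame:
    """One of the packaged inventory tables (1-5) as a DataFrame."""
    if number not in _TABLE_FILES:
        raise ValueError(f"no packaged table {number}; valid: {sorted(_TABLE_FILES)}")
    path = resources.files("ktfam.data.tables").joinpath(_TABLE_FILES[number])
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_all_tables() -> pd.DataFrame:
    return pd.concat([load_table(i) for i in sorted(_TABLE_FILES)], ignore_index=True)


def family_table(family: str) -> pd.DataFrame:
    table = load_all_tables()
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; valid: {FAMILIES}")
    return table[table["family"] == family].reset_index(drop=True)


def _names(family: str, species: str, *numbers_or_names) -> list[str]:
    """Resolve protein names for (family, species); passthrough for full names."""
    table = family_table(family)
    pool = set(table[table["species"] == species]["name"])
    out = []
    for item in numbers_or_names:
        if item in pool:
            out.append(item)
        else:
            raise KeyError(f"{item!r} not a {family} name for {species}")
    return out


# ---------------------------------------------------------------------------
# Ortholog-group structures.  Leaves are the published protein names; the
# nested join structure is given as nested tuples of group names.
# ---------------------------------------------------------------------------

HKT_GROUPS = {
    "G1": "ALL",  # single group of orthologs spanning every species
}
HKT_JOIN = "G1"

TPK_GROUPS = {
    "A": {
        "Athaliana": ["Ara-tha-TPK1", "Ara-tha-TPK2", "Ara-tha-KCO3"],
        "Osativa": ["Ory-sat-TPKa"],
        "Ptrichocarpa": ["Pop-tri-TPK01", "Pop-tri-TPK02", "Pop-tri-TPK03",
                          "Pop-tri-TPK04", "Pop-tri-TPK05"],
        "Ppatens": ["Phy-pat-TPK01", "Phy-pat-TPK02"],
        "Smoellendorffii": ["Sel-moe-TPK1", "Sel-moe-TPK2"],
    },
    "B": {
        "Athaliana": ["Ara-tha-TPK3", "Ara-tha-TPK4", "Ara-tha-TPK5"],
        "Osativa": ["Ory-sat-TPKb", "Ory-sat-TPKc"],
        "Ptrichocarpa": ["Pop-tri-TPK06", "Pop-tri-TPK07", "Pop-tri-TPK08",
                          "Pop-tri-TPK09", "Pop-tri-TPK10"],
        "Ppatens": ["Phy-pat-TPK03"],
        "Smoellendorffii": ["Sel-moe-TPK3", "Sel-moe-TPK4"],
    },
}
TPK_JOIN = ("A", "B")

SHAKER_GROUPS = {
    # bryophyte-specific amplification after the P. patens / tracheophyte split
    "PP": {
        "Ppatens": ["Phy-pat-AKT1", "Phy-pat-AKT2", "Phy-pat-AKT3", "Phy-pat-AKT4"],
    },
    # K_out subunits; Sel-moe-SmORK is the sole S. moellendorffii Shaker gene
    "KOUT": {
        "Athaliana": ["Ara-tha-SKOR", "Ara-tha-GORK"],
        "Osativa": ["Ory-sat-Kc09", "Ory-sat-Kc10"],
        "Ptrichocarpa": ["Pop-tri-Kc10", "Pop-tri-Kc11"],
        "Smoellendorffii": ["Sel-moe-SmORK"],
    },
    # angiosperm K_in / K_weak / K_silent subunits (absent from S. moellendorffii)
    "KIN": {
        "Athaliana": ["Ara-tha-KAT1", "Ara-tha-KAT2", "Ara-tha-AKT1", "Ara-tha-AKT5",
                       "Ara-tha-SPIK", "Ara-tha-AKT2", "Ara-tha-AtKC1"],
        "Osativa": ["Ory-sat-OsAKT1", "Ory-sat-Kc01", "Ory-sat-Kc02", "Ory-sat-Kc03",
                     "Ory-sat-Kc04", "Ory-sat-Kc05", "Ory-sat-Kc06", "Ory-sat-Kc07",
                     "Ory-sat-Kc08"],
        "Ptrichocarpa": ["Pop-tri-Kc01", "Pop-tri-Kc02", "Pop-tri-Kc03", "Pop-tri-Kc04",
                          "Pop-tri-Kc05", "Pop-tri-Kc06", "Pop-tri-Kc07", "Pop-tri-Kc08",
                          "Pop-tri-Kc09"],
    },
}
SHAKER_JOIN = ("PP", ("KOUT", "KIN"))

# Six HAK groups; anchors fixed by the published grouping, the rest a
# reconstruction (groups V and VI are P. patens-specific).
HAK_GROUPS = {
    "I": {
        "Athaliana": ["Ara-tha-HAK5", "Ara-tha-KUP/HAK/KT12"],
        "Osativa": ["Ory-sat-HAK1", "Ory-sat-HAK5"],
        "Ptrichocarpa": ["Pop-tri-HAK1", "Pop-tri-HAK2"],
        "Ppatens": ["Phy-pat-HAK1"],
        "Smoellendorffii": ["Sel-moe-HAK5", "Sel-moe-HAK8", "Sel-moe-HAK9"],
    },
    "II": {
        "Athaliana": ["Ara-tha-KUP/HAK/KT1", "Ara-tha-KUP3"],
        "Osativa": ["Ory-sat-HAK10"],
        "Ptrichocarpa": ["Pop-tri-HAK3", "Pop-tri-HAK4"],
        "Ppatens": ["Phy-pat-HAK2"],
        "Smoellendorffii": ["Sel-moe-HAK2"],
    },
    "III": {
        "Athaliana": ["Ara-tha-KUP4", "Ara-tha-KUP/KT5", "Ara-tha-KUP/HAK/KT6",
                       "Ara-tha-KUP/HAK/KT7"],
        "Osativa": ["Ory-sat-HAK2", "Ory-sat-HAK3", "Ory-sat-HAK4", "Ory-sat-HAK6",
                     "Ory-sat-HAK7", "Ory-sat-HAK8", "Ory-sat-HAK9"],
        "Ptrichocarpa": ["Pop-tri-HAK5", "Pop-tri-HAK6", "Pop-tri-HAK7", "Pop-tri-HAK8",
                          "Pop-tri-HAK9", "Pop-tri-HAK10", "Pop-tri-HAK11", "Pop-tri-HAK12"],
        "Smoellendorffii": ["Sel-moe-HAK3", "Sel-moe-HAK4", "Sel-moe-HAK6",
                             "Sel-moe-HAK7", "Sel-moe-HAK10"],
    },
    "IV": {
        "Athaliana": ["Ara-tha-KUP/HAK/KT2", "Ara-tha-KUP/HAK/KT8", "Ara-tha-KUP/HAK/KT9",
                       "Ara-tha-KUP/HAK/KT10", "Ara-tha-KUP/HAK/KT11"],
        "Osativa": ["Ory-sat-HAK11", "Ory-sat-HAK12", "Ory-sat-HAK13", "Ory-sat-HAK14",
                     "Ory-sat-HAK15", "Ory-sat-HAK16", "Ory-sat-HAK17", "Ory-sat-HAK18",
                     "Ory-sat-HAK19", "Ory-sat-HAK20", "Ory-sat-HAK21", "Ory-sat-HAK22",
                     "Ory-sat-HAK23", "Ory-sat-HAK24", "Ory-sat-HAK25", "Ory-sat-HAK26",
                     "Ory-sat-HAK27"],
        "Ptrichocarpa": ["Pop-tri-HAK13", "Pop-tri-HAK14", "Pop-tri-HAK15", "Pop-tri-HAK16",
                          "Pop-tri-HAK17", "Pop-tri-HAK18", "Pop-tri-HAK19", "Pop-tri-HAK20",
                          "Pop-tri-HAK21", "Pop-tri-HAK22"],
        "Ppatens": ["Phy-pat-HAK13"],
        "Smoellendorffii": ["Sel-moe-HAK1", "Sel-moe-HAK11"],
    },
    "V": {
        "Ppatens": ["Phy-pat-HAK3", "Phy-pat-HAK4", "Phy-pat-HAK5", "Phy-pat-HAK6",
                     "Phy-pat-HAK7", "Phy-pat-HAK8"],
    },
    "VI": {
        "Ppatens": ["Phy-pat-HAK9", "Phy-pat-HAK10", "Phy-pat-HAK11", "Phy-pat-HAK12",
                     "Phy-pat-HAK14", "Phy-pat-HAK15", "Phy-pat-HAK16", "Phy-pat-HAK17",
                     "Phy-pat-HAK18"],
    },
}
HAK_JOIN = ("II", ("V", ("VI", ("I", ("III", "IV")))))

GROUP_STRUCTURES = {
    "HKT": (HKT_GROUPS, HKT_JOIN),
    "TPK": (TPK_GROUPS, TPK_JOIN),
    "SHAKER": (SHAKER_GROUPS, SHAKER_JOIN),
    "HAK": (HAK_GROUPS, HAK_JOIN),
}

#: partial-annotation flag from the published table (asterisked entry)
PARTIAL_SEQUENCES = {"Pop-tri-Kc06"}


def group_members(family: str) -> dict[str, dict[str, list[str]]]:
    """Per-group, per-species protein names for a family.

    The HKT sentinel "ALL" expands to every locus of the family.
    """
    groups, _ = GROUP_STRUCTURES[family]
    table = family_table(family)
    expanded = {}
    for group, members in groups.items():
        if members == "ALL":
            per_species: dict[str, list[str]] = {}
            for _, row in table.iterrows():
                per_species.setdefault(row["species"], []).append(row["name"])
            expanded[group] = per_species
        else:
            expanded[group] = {sp: list(names) for sp, names in members.items()}
    # sanity: the groups partition the family table exactly
    claimed = [n for g in expanded.values() for names in g.values() for n in names]
    if sorted(claimed) != sorted(table["name"]):
        missing = set(table["name"]) - set(claimed)
        extra = set(claimed) - set(table["name"])
        raise ValueError(
            f"{family} group structure does not partition the table "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    return expanded


def species_of_name(family: str) -> dict[str, str]:
    table = family_table(family)
    return dict(zip(table["name"], table["species"]))
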