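"""PED-like pedigree tables and truth-table round trips.

The pedigree format is a TSV with one trio per row: trio_id,
offspring_id, sire_id, dam_id, offspring_sex (M/F), paternal and
maternal ages at conception (years), breed, size_class, per-individual
mean depths, litter_id, pedigree_id.
"""

from __future__ import annotations

import pandas as pd

from canidnm.records import TrioRecord

PED_COLUMNS = [
    "trio_id",
    "offspring_id",
    "sire_id",
    "dam_id",
    "offspring_sex",
    "paternal_age_years",
    "maternal_age_years",
    "breed",
    "size_class",
    "offspring_depth",
    "sire_depth",
    "dam_depth",
    "litter_id",
    "pedigree_id",
]


def write_pedigree(trios, path) -> None:
    rows = [
        {
            "trio_id": t.trio_id,
            "offspring_id": t.offspring_id,
            "sire_id": t.sire_id,
            "dam_id": t.dam_id,
            "offspring_sex": t.offspring_sex,
            "paternal_age_years": t.paternal_age_years,
            "maternal_age_years": t.maternal_age_years,
            "breed": t.breed,
            "size_class": t.size_class,
            "offspring_depth": t.mean_depth["offspring"],
            "sire_depth": t.mean_depth["sire"],
            "dam_depth": t.mean_depth["dam"],
            "litter_id": t.litter_id,
            "pedigree_id": t.pedigree_id,
        }
        for t in trios
    ]
    pd.DataFrame(rows, columns=PED_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_pedigree(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"trio_id": str})
    missing = set(PED_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    trios = []
    for row in df.itertuples(index=False):
        trios.append(
            TrioRecord(
                trio_id=str(row.trio_id),
                offspring_id=str(row.offspring_id),
                sire_id=str(row.sire_id),
                dam_id=str(row.dam_id),
                offspring_sex=str(row.offspring_sex),
                paternal_age_years=float(row.paternal_age_years),
                maternal_age_years=float(row.maternal_age_years),
                breed=str(getattr(row, "breed", "unknown")),
                size_class=str(getattr(row, "size_class", "intermediate")),
                mean_depth={
                    "offspring": float(getattr(row, "offspring_depth", 40.0)),
                    "sire": float(getattr(row, "sire_depth", 40.0)),
                    "dam": float(getattr(row, "dam_depth", 40.0)),
                },
                litter_id=str(getattr(row, "litter_id", "")),
                pedigree_id=str(getattr(row, "pedigree_id", "")),
            )
        )
    if len({t.trio_id for t in trios}) != len(trios):
        raise ValueError("trio_id values must be unique within a cohort")
    return trios
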