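"""Chloroplast (cytoplasm) typing from CAPS digestion patterns.

Each CAPS marker's observed fragment pattern maps to a haplotype letter;
the tuple of letters across the declared markers maps to one of the four
maternal-lineage types Ia, Ib, Ic, III.  The concrete key (marker names,
patterns, tuple->type table) is user-supplied configuration, since it is
assay-specific; :mod:`melodiv.simulate` emits a matching synthetic key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .data_model import AccessionRecord, DataError
from .genetic_stats import ContingencyTable
from .traits import classify_seed

__all__ = [
    "CYTOPLASM_TYPES",
    "CytoplasmKey",
    "CytoplasmTypeTable",
    "classify_cytoplasm",
    "type_by_group_crosstab",
]

CYTOPLASM_TYPES = ("Ia", "Ib", "Ic", "III")
UNCLASSIFIED = "unclassified"


@dataclass
class CytoplasmKey:
    """Declarative mapping: marker pattern -> allele letter; letter tuple -> type."""

    markers: list[str]
    pattern_map: dict[str, dict[str, str]]
    type_map: dict[tuple[str, ...], str]

    def __post_init__(self) -> None:
        for mk in self.markers:
            if mk not in self.pattern_map:
                raise DataError(f"cytoplasm key: marker {mk!r} has no pattern map")
        for haplo, ctype in self.type_map.items():
            if len(haplo) != len(self.markers):
                raise DataError(
                    f"cytoplasm key: haplotype {haplo} does not cover the "
                    f"{len(self.markers)} declared markers"
                )
            if ctype not in CYTOPLASM_TYPES:
                raise DataError(
                    f"cytoplasm key: type {ctype!r} not one of {CYTOPLASM_TYPES}"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "CytoplasmKey":
        markers = [str(m) for m in data["markers"]]
        pattern_map = {
            str(mk): {str(p): str(a) for p, a in pm.items()}
            for mk, pm in data["pattern_map"].items()
        }
        type_map = {
            tuple(s.strip() for s in str(h).split(",")): str(t)
            for h, t in data["type_map"].items()
        }
        return cls(markers=markers, pattern_map=pattern_map, type_map=type_map)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CytoplasmKey":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "pattern_map": {m: dict(pm) for m, pm in self.pattern_map.items()},
            "type_map": {",".join(h): t for h, t in self.type_map.items()},
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CytoplasmTypeTable:
    """Per-accession cytoplasm type with reasons for unclassified calls."""

    types: pd.Series  # accession -> type or "unclassified"
    reasons: dict[str, str]

    def __getitem__(self, accession: str) -> str:
        return str(self.types.loc[accession])


def classify_cytoplasm(
    calls: pd.DataFrame | Mapping[str, Mapping[str, str]],
    key: CytoplasmKey,
) -> CytoplasmTypeTable:
    """Map each accession's CAPS patterns to a cytoplasm type.

    ``calls``: accession x marker table of observed pattern labels.  An
    unknown pattern is a hard error (it indicates a key/assay mismatch); a
    missing marker call or a haplotype tuple absent from the key leaves the
    accession "unclassified" with a recorded reason.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame.from_dict({a: dict(m) for a, m in calls.items()}, orient="index")
    missing_markers = [m for m in key.markers if m not in calls.columns]
    if missing_markers:
        raise DataError(f"call table lacks declared marker(s): {missing_markers}")

    types: dict[str, str] = {}
    reasons: dict[str, str] = {}
    for acc, row in calls.iterrows():
        letters = []
        reason = None
        for mk in key.markers:
            pat = row[mk]
            if pd.isna(pat) or str(pat) in ("", "."):
                reason = f"missing call at marker {mk!r}"
                break
            pat = str(pat)
            if pat not in key.pattern_map[mk]:
                raise DataError(
                    f"accession {acc!r}: pattern {pat!r} at marker {mk!r} "
                    "not in the cytoplasm key"
                )
            letters.append(key.pattern_map[mk][pat])
        if reason is not None:
            types[str(acc)] = UNCLASSIFIED
            reasons[str(acc)] = reason
            continue
        haplo = tuple(letters)
        ctype = key.type_map.get(haplo)
        if ctype is None:
            types[str(acc)] = UNCLASSIFIED
            reasons[str(acc)] = f"haplotype {'/'.join(haplo)} absent from type map"
        else:
            types[str(acc)] = ctype
    series = pd.Series(types, name="cytoplasm_type")
    series = series.loc[[str(a) for a in calls.index]]  # preserve input order
    return CytoplasmTypeTable(types=series, reasons=reasons)


def type_by_group_crosstab(
    types: CytoplasmTypeTable,
    meta: Iterable[AccessionRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Count accessions by region/group x seed class x cytoplasm type.

    Returns a table with one row per region/group and hierarchical columns
    (seed class, cytoplasm type), plus the list of typed accessions that
    were excluded for lacking metadata or a seed length.
    """
    by_id = {r.id: r for r in meta}
    rows = []
    excluded = []
    for acc, ctype in types.types.items():
        rec = by_id.get(str(acc))
        if rec is None or rec.seed_length_mm is None:
            excluded.append(str(acc))
            continue
        rows.append(
            {
                "region_group": rec.region_group,
                "seed_class": classify_seed(rec.seed_length_mm),
                "cytoplasm_type": ctype,
            }
        )
    if not rows:
        raise DataError("no typed accession has usable metadata")
    df = pd.DataFrame(rows)
    table = pd.crosstab(
        df["region_group"], [df["seed_class"], df["cytoplasm_type"]]
    )
    type_order = [t for t in (*CYTOPLASM_TYPES, UNCLASSIFIED)]
    cols = [
        (sc, ct)
        for sc in ("large", "small")
        for ct in type_order
        if (sc, ct) in table.columns
    ]
    return table.loc[:, cols], excluded


def crosstab_to_contingency(table: pd.DataFrame) -> ContingencyTable:
    """Flatten a crosstab into a plain ContingencyTable (rows x flat columns)."""
    col_labels = [
        "/".join(str(p) for p in c) if isinstance(c, tuple) else str(c)
        for c in table.columns
    ]
    return ContingencyTable(
        row_labels=[str(r) for r in table.index],
        col_labels=col_labels,
        counts=table.to_numpy(),
    )
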