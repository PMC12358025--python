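"""Domain types and I/O for mixed dominant/codominant marker datasets.

The marker panel mixes two scoring conventions that are common in older
germplasm surveys:

* **dominant** markers (e.g. RAPD bands) are scored as band present / band
  absent and entered as pseudo-homozygous genotypes ``1/1`` / ``0/0``;
* **codominant** markers (e.g. SSRs) are scored as allele *size ranks*
  (1 = smallest fragment) and entered as unordered allele pairs such as
  ``2/2`` (homozygote) or ``3/7`` (heterozygote).

All downstream statistics consume exactly this coding; no Hardy–Weinberg
back-estimation is attempted for dominant markers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "MarkerDef",
    "Genotype",
    "GenotypeMatrix",
    "AccessionRecord",
    "DistanceMatrix",
    "ValidationReport",
    "load_dataset",
    "load_genotype_matrix",
    "load_metadata",
    "load_panel",
    "load_trait_table",
    "validate_dataset",
    "write_distance_phylip",
    "read_distance_phylip",
    "write_genotype_matrix",
]

MISSING = -1

DOMINANT = "dominant"
CODOMINANT = "codominant"


class DataError(ValueError):
    """Raised for malformed input tables, with row/column context."""


@dataclass(frozen=True)
class MarkerDef:
    """A marker in the panel.

    Dominant markers carry the implicit two-state band {absent=0, present=1};
    codominant markers carry explicit allele labels (size ranks as strings).
    """

    name: str
    kind: str
    chromosome: str | None = None
    allele_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (DOMINANT, CODOMINANT):
            raise DataError(f"marker {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == DOMINANT and self.allele_labels:
            raise DataError(
                f"marker {self.name!r}: dominant markers have the implicit "
                "band states and take no allele labels"
            )

    @property
    def is_dominant(self) -> bool:
        return self.kind == DOMINANT


@dataclass(frozen=True, order=True)
class Genotype:
    """One diploid call: an unordered allele pair, stored sorted.

    For dominant markers only the pseudo-homozygotes 1/1 (band present) and
    0/0 (band absent) are representable.
    """

    allele_a: int
    allele_b: int
    missing: bool = False

    @classmethod
    def from_token(cls, token: str, kind: str) -> "Genotype":
        token = token.strip()
        if token in (".", "", "./.", "NA"):
            return cls(MISSING, MISSING, missing=True)
        parts = token.split("/")
        if len(parts) == 1:
            parts = [parts[0], parts[0]]
        if len(parts) != 2:
            raise DataError(f"malformed genotype token {token!r}")
        try:
            a, b = (int(p) for p in parts)
        except ValueError as exc:
            raise DataError(f"malformed genotype token {token!r}") from exc
        if kind == DOMINANT:
            if (a, b) not in ((0, 0), (1, 1)):
                raise DataError(
                    f"dominant marker call {token!r}: only 1/1 or 0/0 allowed "
                    "(a dominant heterozygote is not observable)"
                )
        elif a > b:
            a, b = b, a
        return cls(a, b)

    @property
    def token(self) -> str:
        if self.missing:
            return "."
        return f"{self.allele_a}/{self.allele_b}"

    @property
    def alleles(self) -> tuple[int, ...]:
        """Distinct alleles carried (empty when missing)."""
        if self.missing:
            return ()
        if self.allele_a == self.allele_b:
            return (self.allele_a,)
        return (self.allele_a, self.allele_b)

    @property
    def is_heterozygote(self) -> bool:
        return not self.missing and self.allele_a != self.allele_b


@dataclass
class GenotypeMatrix:
    """Accessions x markers grid of genotype calls.

    ``calls`` has shape (n_accessions, n_markers, 2) holding sorted allele
    codes, with :data:`MISSING` (-1) in both slots for missing cells.
    """

    accessions: list[str]
    markers: list[MarkerDef]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.accessions), len(self.markers)
        if self.calls.shape != (n, m, 2):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} accessions x {m} markers"
            )
        if len(set(self.accessions)) != n:
            raise DataError("accession IDs are not unique")
        names = [mk.name for mk in self.markers]
        if len(set(names)) != m:
            raise DataError("marker names are not unique")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_accessions, n_markers) mask of missing cells."""
        return self.calls[:, :, 0] == MISSING

    def get(self, accession: int | str, marker: int | str) -> Genotype:
        i = self.accession_index(accession)
        j = self.marker_index(marker)
        a, b = self.calls[i, j]
        if a == MISSING:
            return Genotype(MISSING, MISSING, missing=True)
        return Genotype(int(a), int(b))

    def accession_index(self, accession: int | str) -> int:
        if isinstance(accession, str):
            try:
                return self.accessions.index(accession)
            except ValueError:
                raise DataError(f"unknown accession {accession!r}") from None
        return int(accession)

    def marker_index(self, marker: int | str) -> int:
        if isinstance(marker, str):
            for j, mk in enumerate(self.markers):
                if mk.name == marker:
                    return j
            raise DataError(f"unknown marker {marker!r}")
        return int(marker)

    def marker_kinds(self) -> np.ndarray:
        return np.array([mk.is_dominant for mk in self.markers])

    def subset_markers(self, kind: str) -> "GenotypeMatrix":
        """Restrict to markers of one kind (dominant or codominant)."""
        idx = [j for j, mk in enumerate(self.markers) if mk.kind == kind]
        return GenotypeMatrix(
            accessions=list(self.accessions),
            markers=[self.markers[j] for j in idx],
            calls=self.calls[:, idx, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Genotype tokens as a DataFrame (accessions x markers)."""
        data = {}
        for j, mk in enumerate(self.markers):
            col = []
            for i in range(self.n_accessions):
                a, b = self.calls[i, j]
                col.append("." if a == MISSING else f"{a}/{b}")
            data[mk.name] = col
        return pd.DataFrame(data, index=pd.Index(self.accessions, name="accession"))


@dataclass(frozen=True)
class AccessionRecord:
    """Passport metadata for one accession."""

    id: str
    region_group: str
    seed_length_mm: float | None = None
    seed_width_mm: float | None = None
    horticultural_group: str | None = None

    def __post_init__(self) -> None:
        for attr in ("seed_length_mm", "seed_width_mm"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise DataError(f"accession {self.id!r}: {attr} must be > 0, got {v}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[int | str, int | str]) -> float:
        i, j = (self.labels.index(p) if isinstance(p, str) else p for p in pair)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ValidationReport:
    """Report-only dataset validation outcome."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.errors and not self.warnings

    def __str__(self) -> str:  # pragma: no cover - convenience only
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "(dataset consistent)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def load_panel(path: str | Path) -> list[MarkerDef]:
    """Read a marker-panel table (columns: marker, kind, [chromosome], [alleles]).

    ``alleles`` is a comma-separated list of allele labels for codominant
    markers; when omitted the labels are inferred from the genotype data.
    """
    df = _read_table(path)
    required = {"marker", "kind"}
    if not required.issubset(df.columns):
        raise DataError(f"panel file must have columns {sorted(required)}")
    panel = []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip().lower()
        if kind not in (DOMINANT, CODOMINANT):
            raise DataError(
                f"marker {row['marker']!r}: unknown marker kind {row['kind']!r}"
            )
        alleles: tuple[str, ...] = ()
        if kind == CODOMINANT and "alleles" in df.columns and pd.notna(row.get("alleles")):
            alleles = tuple(s.strip() for s in str(row["alleles"]).split(",") if s.strip())
        chrom = None
        if "chromosome" in df.columns and pd.notna(row.get("chromosome")):
            chrom = str(row["chromosome"])
        panel.append(MarkerDef(str(row["marker"]), kind, chrom, alleles))
    return panel


def load_genotype_matrix(path: str | Path, panel: Sequence[MarkerDef]) -> GenotypeMatrix:
    """Read a genotype table (first column accession, then one column per marker)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise DataError("genotype table needs an accession column plus markers")
    acc_col = df.columns[0]
    by_name = {mk.name: mk for mk in panel}
    marker_cols = [c for c in df.columns[1:]]
    unknown = [c for c in marker_cols if c not in by_name]
    if unknown:
        raise DataError(f"genotype columns not declared in panel: {unknown}")
    markers = [by_name[c] for c in marker_cols]
    accessions = [str(a) for a in df[acc_col]]
    n, m = len(accessions), len(markers)
    calls = np.full((n, m, 2), MISSING, dtype=np.int64)
    for j, mk in enumerate(markers):
        allowed = {int(lab) for lab in mk.allele_labels} if mk.allele_labels else None
        col = df[marker_cols[j]]
        for i in range(n):
            raw = col.iloc[i]
            token = "." if pd.isna(raw) else str(raw)
            try:
                gt = Genotype.from_token(token, mk.kind)
            except DataError as exc:
                raise DataError(
                    f"row {accessions[i]!r}, marker {mk.name!r}: {exc}"
                ) from None
            if gt.missing:
                continue
            if allowed is not None and not set(gt.alleles) <= allowed:
                raise DataError(
                    f"row {accessions[i]!r}, marker {mk.name!r}: allele token "
                    f"{token!r} not in panel alleles {sorted(allowed)}"
                )
            calls[i, j] = (gt.allele_a, gt.allele_b)
    return GenotypeMatrix(accessions, markers, calls)


def load_metadata(path: str | Path) -> list[AccessionRecord]:
    """Read accession metadata (accession, region_group, seed_length_mm, ...)."""
    df = _read_table(path)
    if "accession" not in df.columns or "region_group" not in df.columns:
        raise DataError("metadata must have 'accession' and 'region_group' columns")

    def _num(row: pd.Series, col: str) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    records = []
    for _, row in df.iterrows():
        records.append(
            AccessionRecord(
                id=str(row["accession"]),
                region_group=str(row["region_group"]),
                seed_length_mm=_num(row, "seed_length_mm"),
                seed_width_mm=_num(row, "seed_width_mm"),
                horticultural_group=(
                    str(row["horticultural_group"])
                    if "horticultural_group" in row and pd.notna(row.get("horticultural_group"))
                    else None
                ),
            )
        )
    return records


def load_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a quantitative trait table (accession x traits) as floats."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return df.astype(float)


def load_dataset(
    genotype_path: str | Path,
    metadata_path: str | Path,
    panel_path: str | Path,
) -> tuple[GenotypeMatrix, list[AccessionRecord]]:
    """Load and validate genotype matrix plus accession metadata."""
    panel = load_panel(panel_path)
    g = load_genotype_matrix(genotype_path, panel)
    meta = load_metadata(metadata_path)
    return g, meta


def validate_dataset(
    g: GenotypeMatrix, meta: Iterable[AccessionRecord]
) -> ValidationReport:
    """Cross-check a genotype matrix against its metadata; report-only."""
    report = ValidationReport()
    meta = list(meta)
    ids = [r.id for r in meta]
    seen: set[str] = set()
    for acc in ids:
        if acc in seen:
            report.errors.append(f"duplicated accession ID in metadata: {acc!r}")
        seen.add(acc)
    meta_ids = set(ids)
    for acc in g.accessions:
        if acc not in meta_ids:
            report.warnings.append(f"accession {acc!r} missing from metadata")
    miss = g.missing_mask
    for j, mk in enumerate(g.markers):
        if miss[:, j].all():
            report.warnings.append(f"marker {mk.name!r} has all-missing calls")
    return report


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix back to TSV ('a/b' tokens, '.' for missing)."""
    g.to_frame().to_csv(path, sep="\t")


_PHYLIP_NAME_WIDTH = 10


def write_distance_phylip(d: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (10-character name field)."""
    short = [lab[:_PHYLIP_NAME_WIDTH] for lab in d.labels]
    if len(set(short)) != len(short):
        dupes = sorted({s for s in short if short.count(s) > 1})
        raise DataError(
            f"taxon names collide after truncation to {_PHYLIP_NAME_WIDTH} "
            f"characters: {dupes}"
        )
    with open(path, "w") as fh:
        fh.write(f"{d.n}\n")
        for name, row in zip(short, d.values):
            cells = "  ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name:<{_PHYLIP_NAME_WIDTH}}{cells}\n")


def read_distance_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_distance_phylip`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        labels.append(ln[:_PHYLIP_NAME_WIDTH].strip())
        rows.append([float(v) for v in ln[_PHYLIP_NAME_WIDTH:].split()])
    values = np.asarray(rows)
    # symmetrize away formatting round-off
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)
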