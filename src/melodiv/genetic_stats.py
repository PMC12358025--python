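"""Band-sharing similarity, genetic distance, and diversity statistics.

Pairwise similarity follows the band-sharing convention for a mixed
dominant/codominant panel:

    GS(i, j) = (N11 + N00) / n_markers

where ``N11`` accumulates shared positive band scores (a half-shared SSR
heterozygote pair such as 2/2 vs 2/3 contributes 0.5), ``N00`` counts shared
dominant-band absences, and the denominator is the number of mutually
non-missing markers (with complete data, the full panel size).  Genetic
distance is GD = 1 - GS.

Group-level statistics (PIC, gene diversity, Nei's 1972 standard distance)
operate on allele frequencies computed from the same pseudo-homozygote
coding the matrix stores: dominant markers contribute the two-state
frequencies of their 1/1 vs 0/0 codes, with no Hardy-Weinberg
back-estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .data_model import (
    DOMINANT,
    MISSING,
    DataError,
    DistanceMatrix,
    Genotype,
    GenotypeMatrix,
)

__all__ = [
    "DistanceMatrix",
    "ShareResult",
    "SimilarityComponents",
    "AlleleFreqTable",
    "ContingencyTable",
    "ChiSquareResult",
    "marker_share",
    "gs_pair",
    "gs_components",
    "gs_matrix",
    "gd_matrix",
    "allele_freqs",
    "pic",
    "gene_diversity",
    "nei_distance_1972",
    "chi_square_independence",
]

POSITIVE = "positive"
NULL = "null"
MISMATCH = "mismatch"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ShareResult:
    score: float
    channel: str


@dataclass(frozen=True)
class SimilarityComponents:
    """N11/N00 decomposition of one pairwise comparison."""

    n11: float
    n00: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.n11 + self.n00 > self.n_markers + 1e-9:
            raise DataError("n11 + n00 exceeds the marker count")

    @property
    def gs(self) -> float:
        return (self.n11 + self.n00) / self.n_markers


def marker_share(gi: Genotype, gj: Genotype, kind: str) -> ShareResult:
    """Per-marker band-sharing score between two calls.

    Dominant: both bands present -> (1, positive); both absent -> (1, null);
    otherwise (0, mismatch).  Codominant: score = |A∩B| / max(|A|,|B|) over
    distinct-allele sets, so a homozygote vs an overlapping heterozygote
    (2/2 vs 2/3) shares 0.5.
    """
    if gi.missing or gj.missing:
        return ShareResult(0.0, EXCLUDED)
    if kind == DOMINANT:
        if gi.allele_a == gj.allele_a:
            return ShareResult(1.0, POSITIVE if gi.allele_a == 1 else NULL)
        return ShareResult(0.0, MISMATCH)
    a, b = set(gi.alleles), set(gj.alleles)
    score = len(a & b) / max(len(a), len(b))
    return ShareResult(score, POSITIVE if score > 0 else MISMATCH)


def gs_components(
    g: GenotypeMatrix, i: int | str, j: int | str
) -> SimilarityComponents:
    """N11, N00 and the pairwise-deletion denominator for one accession pair."""
    ii, jj = g.accession_index(i), g.accession_index(j)
    n11 = 0.0
    n00 = 0
    n_used = 0
    for m, mk in enumerate(g.markers):
        res = marker_share(g.get(ii, m), g.get(jj, m), mk.kind)
        if res.channel == EXCLUDED:
            continue
        n_used += 1
        if res.channel == NULL:
            n00 += 1
        else:
            n11 += res.score
    if n_used == 0:
        raise DataError(
            f"accessions {g.accessions[ii]!r} and {g.accessions[jj]!r} share "
            "no mutually non-missing markers"
        )
    return SimilarityComponents(n11=n11, n00=n00, n_markers=n_used)


def gs_pair(g: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Band-sharing genetic similarity GS = (N11 + N00) / n for one pair."""
    return gs_components(g, i, j).gs


def _share_cube(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-locus share scores for all accession pairs.

    Returns (scores, valid): both (n, n, L); ``valid`` marks mutually
    non-missing cells.
    """
    a1 = g.calls[:, :, 0]  # (n, L)
    a2 = g.calls[:, :, 1]
    present = a1 != MISSING
    valid = present[:, None, :] & present[None, :, :]

    x1, x2 = a1[:, None, :], a2[:, None, :]
    y1, y2 = a1[None, :, :], a2[None, :, :]
    dom = g.marker_kinds()[None, None, :]

    # codominant: |A ∩ B| / max(|A|, |B|) over distinct-allele sets
    first_in = (x1 == y1) | (x1 == y2)
    second_in = (x2 != x1) & ((x2 == y1) | (x2 == y2))
    inter = first_in.astype(float) + second_in.astype(float)
    size_x = 1 + (x2 != x1)
    size_y = 1 + (y2 != y1)
    codom_score = inter / np.maximum(size_x, size_y)

    dom_score = (x1 == y1).astype(float)
    scores = np.where(dom, dom_score, codom_score)
    return np.where(valid, scores, 0.0), valid


def gs_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """All pairwise GS values (pairwise-deletion denominator under missingness)."""
    scores, valid = _share_cube(g)
    denom = valid.sum(axis=2)
    if (denom == 0).any():
        bad = np.argwhere((denom == 0) & ~np.eye(g.n_accessions, dtype=bool))
        if len(bad):
            i, j = bad[0]
            raise DataError(
                f"accessions {g.accessions[i]!r} and {g.accessions[j]!r} share "
                "no mutually non-missing markers"
            )
        denom = np.maximum(denom, 1)
    gs = scores.sum(axis=2) / np.maximum(denom, 1)
    np.fill_diagonal(gs, 1.0)
    return pd.DataFrame(gs, index=g.accessions, columns=g.accessions)


def gd_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise genetic distance GD = 1 - GS."""
    if g.n_accessions < 2:
        raise DataError("need at least 2 accessions for a distance matrix")
    gs = gs_matrix(g).to_numpy()
    gd = 1.0 - gs
    gd = (gd + gd.T) / 2.0
    np.fill_diagonal(gd, 0.0)
    return DistanceMatrix(list(g.accessions), gd)


# ---------------------------------------------------------------------------
# allele frequencies and diversity
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Per-group, per-marker allele frequency vectors.

    ``freqs[group][marker]`` is a Series indexed by allele code; markers for
    which a group has no data are absent from that group's mapping.
    """

    freqs: dict[str, dict[str, pd.Series]]
    sample_sizes: dict[str, int]
    marker_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return list(self.freqs)

    def vector(self, group: str, marker: str) -> pd.Series:
        if group not in self.freqs:
            raise DataError(f"unknown group {group!r}")
        if marker not in self.freqs[group]:
            raise DataError(f"group {group!r} has no data for marker {marker!r}")
        return self.freqs[group][marker]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for grp, per_marker in self.freqs.items():
            for marker, vec in per_marker.items():
                for allele, f in vec.items():
                    rows.append((grp, marker, allele, f))
        return pd.DataFrame(rows, columns=["group", "marker", "allele", "frequency"])


def allele_freqs(
    g: GenotypeMatrix, grouping: Mapping[str, str] | None = None
) -> AlleleFreqTable:
    """Allele frequencies per group and marker.

    Codominant markers are counted over 2n gene copies; dominant markers
    contribute the frequencies of their 1/1 vs 0/0 codes (allele code 1 =
    band present).  ``grouping`` maps accession ID to group label; omitted
    accessions are skipped, and ``None`` pools everything into "all".
    """
    if grouping is None:
        grouping = {acc: "all" for acc in g.accessions}
    groups: dict[str, list[int]] = {}
    for i, acc in enumerate(g.accessions):
        if acc in grouping:
            groups.setdefault(grouping[acc], []).append(i)
    if not groups:
        raise DataError("grouping matches no accession in the matrix")
    for grp, idx in groups.items():
        if not idx:
            raise DataError(f"group {grp!r} is empty")

    freqs: dict[str, dict[str, pd.Series]] = {}
    kinds = {mk.name: mk.kind for mk in g.markers}
    for grp, idx in groups.items():
        per_marker: dict[str, pd.Series] = {}
        for j, mk in enumerate(g.markers):
            sub = g.calls[idx, j, :]  # (n_g, 2)
            sub = sub[sub[:, 0] != MISSING]
            if sub.size == 0:
                continue  # all-missing: vector flagged absent for this marker
            if mk.is_dominant:
                # one code per accession (pseudo-homozygote), two states 0/1
                states = sub[:, 0]
                counts = pd.Series(states).value_counts().sort_index()
            else:
                counts = pd.Series(sub.ravel()).value_counts().sort_index()
            vec = counts / counts.sum()
            vec.index.name = "allele"
            per_marker[mk.name] = vec
        freqs[grp] = per_marker
    sizes = {grp: len(idx) for grp, idx in groups.items()}
    return AlleleFreqTable(freqs=freqs, sample_sizes=sizes, marker_kinds=kinds)


def pic(freqs: Sequence[float] | pd.Series, kind: str) -> float:
    """Polymorphic information content of one marker.

    Codominant (Botstein): PIC = 1 - Σp_i² - Σ_{i<j} 2 p_i² p_j².
    Dominant (two-state): PIC = 2p(1-p), whose maximum is 0.5 at p = 0.5.
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise DataError("empty frequency vector")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise DataError(f"frequencies sum to {p.sum()}, not 1")
    if kind == DOMINANT:
        if p.size > 2:
            raise DataError("dominant markers have at most two states")
        band = p[0] if p.size == 1 else p[1]
        return float(2.0 * band * (1.0 - band))
    sum_sq = float(np.sum(p**2))
    p2 = p**2
    cross = float((np.sum(p2) ** 2 - np.sum(p2**2)) / 2.0)  # Σ_{i<j} p_i² p_j²
    return 1.0 - sum_sq - 2.0 * cross


def _locus_h(vec: pd.Series) -> float:
    p = vec.to_numpy(dtype=float)
    return float(1.0 - np.sum(p**2))


def gene_diversity(
    table: AlleleFreqTable,
    group: str,
    markers: Sequence[str] | None = None,
    unbiased: bool = False,
) -> float:
    """Gene diversity D: mean over loci of h = 1 - Σp_i².

    ``unbiased`` applies the small-sample factor 2n/(2n-1) per locus
    (off by default; the plain estimator is the primary definition).
    ``markers`` restricts the average, e.g. to the dominant or codominant
    half of the panel.
    """
    if group not in table.freqs:
        raise DataError(f"unknown group {group!r}")
    per_marker = table.freqs[group]
    names = list(per_marker) if markers is None else [m for m in markers if m in per_marker]
    if not names:
        raise DataError(f"group {group!r} has no loci with data in the requested set")
    n = table.sample_sizes.get(group, 0)
    hs = []
    for m in names:
        h = _locus_h(per_marker[m])
        if unbiased and n > 0:
            h *= (2 * n) / (2 * n - 1)
        hs.append(h)
    return float(np.mean(hs))


def nei_distance_1972(table: AlleleFreqTable, group_a: str, group_b: str) -> float:
    """Nei's (1972) standard genetic distance between two groups.

    D = -ln I with I = Jxy / sqrt(Jx Jy), where Jx, Jy, Jxy are the means
    over shared loci of Σp², Σq², Σpq.  Returns +inf when the groups share
    no alleles at any common locus (I = 0).
    """
    for grp in (group_a, group_b):
        if grp not in table.freqs:
            raise DataError(f"unknown group {grp!r}")
    fa, fb = table.freqs[group_a], table.freqs[group_b]
    shared = [m for m in fa if m in fb]
    if not shared:
        raise DataError(
            f"groups {group_a!r} and {group_b!r} share no locus with data"
        )
    jx, jy, jxy = [], [], []
    for m in shared:
        pa, pb = fa[m], fb[m]
        alleles = pa.index.union(pb.index)
        p = pa.reindex(alleles, fill_value=0.0).to_numpy(dtype=float)
        q = pb.reindex(alleles, fill_value=0.0).to_numpy(dtype=float)
        jx.append(np.sum(p**2))
        jy.append(np.sum(q**2))
        jxy.append(np.sum(p * q))
    i_xy = float(np.mean(jxy)) / math.sqrt(float(np.mean(jx)) * float(np.mean(jy)))
    if i_xy <= 0.0:
        return math.inf
    return max(0.0, -math.log(min(i_xy, 1.0)))


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Counts of accessions cross-classified by two factors."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("contingency counts shape does not match labels")
        if (self.counts < 0).any():
            raise DataError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def chi_square_independence(t: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = t.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DataError("contingency table needs at least 2 rows and 2 columns")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DataError("contingency table has a zero row or column sum")
    stat, p, df, _ = _scipy_stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), pvalue=float(p))
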