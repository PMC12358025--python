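"""Seed-size classification and the morphological analysis chain.

Seed classes follow the conventional 9.0 mm seed-length cut for melon
(large >= 9.0 mm, small < 9.0 mm).  Morphological clustering standardizes
the trait table, takes Euclidean distances, and agglomerates by UPGMA so
the morphological and marker-based dendrograms use the same linkage.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import AccessionRecord, DataError, DistanceMatrix
from .clustering import UltrametricTree, cut_tree, standardize, upgma
from .genetic_stats import ContingencyTable

__all__ = [
    "SEED_LENGTH_CUT_MM",
    "classify_seed",
    "seed_class_table",
    "trait_distance",
    "morph_cluster",
]

SEED_LENGTH_CUT_MM = 9.0

# the 16 standard quantitative/ordinal traits of the survey protocol
TRAIT_NAMES = [
    "seed_length",
    "seed_width",
    "leaf_length",
    "leaf_width",
    "petiole_length",
    "internode_length",
    "flower_type",
    "fruit_weight",
    "fruit_length",
    "fruit_diameter",
    "flesh_thickness",
    "flesh_color",
    "exocarp_color",
    "exocarp_dots",
    "fruit_groove",
    "brix",
]


def classify_seed(length_mm: float) -> str:
    """'large' for seed length >= 9.0 mm, 'small' below; boundary inclusive."""
    if length_mm is None or not np.isfinite(length_mm) or length_mm <= 0:
        raise DataError(f"seed length must be a positive number, got {length_mm!r}")
    return "large" if length_mm >= SEED_LENGTH_CUT_MM else "small"


def seed_class_table(
    meta: Iterable[AccessionRecord],
    grouping: Callable[[AccessionRecord], str] | None = None,
) -> ContingencyTable:
    """Region/group x {large, small} counts, ready for a chi-square test.

    ``grouping`` extracts the row label (default: the region_group field).
    Accessions without a seed length are skipped.
    """
    if grouping is None:
        grouping = lambda r: r.region_group  # noqa: E731
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for rec in meta:
        if rec.seed_length_mm is None:
            continue
        grp = grouping(rec)
        if grp not in counts:
            counts[grp] = {"large": 0, "small": 0}
            order.append(grp)
        counts[grp][classify_seed(rec.seed_length_mm)] += 1
    if not counts:
        raise DataError("no accession has a seed length")
    table = np.array([[counts[g]["large"], counts[g]["small"]] for g in order])
    return ContingencyTable(row_labels=order, col_labels=["large", "small"], counts=table)


def trait_distance(traits: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between accessions on standardized traits."""
    z = standardize(traits)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix([str(i) for i in traits.index], d)


def morph_cluster(
    traits: pd.DataFrame, n_clusters: int
) -> tuple[pd.Series, UltrametricTree]:
    """Standardize -> Euclidean distance -> UPGMA -> cut into n clusters."""
    if traits.shape[0] < 2:
        raise DataError("morphological clustering needs at least 2 accessions")
    tree = upgma(trait_distance(traits))
    labels = cut_tree(tree, n_clusters)
    series = pd.Series(
        [labels[str(i)] for i in traits.index],
        index=traits.index,
        name="morph_cluster",
    )
    return series, tree
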