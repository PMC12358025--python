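"""Synthetic germplasm datasets with known ground truth.

The generator emulates the statistical structure a mixed-marker diversity
survey assumes: K ancestral populations whose allele frequencies diverge
from a common ancestral pool under a drift parameter F (the correlated
allele-frequency model), Dirichlet admixture proportions (or pure
populations), ancestry-linked chloroplast haplotypes, and a bimodal seed
length distribution with a controlled seed-length/fruit-weight correlation.

Every stage of the pipeline can be run end-to-end on the emitted tables,
and the :class:`SimTruth` bookkeeping gives tests exact expected answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cytoplasm import CYTOPLASM_TYPES, CytoplasmKey
from .data_model import (
    AccessionRecord,
    DataError,
    GenotypeMatrix,
    MarkerDef,
    write_genotype_matrix,
)
from .genetic_stats import ContingencyTable
from .traits import SEED_LENGTH_CUT_MM, TRAIT_NAMES

__all__ = [
    "SimSpec",
    "SimTruth",
    "SimulatedDataset",
    "gen_admixed_genotypes",
    "gen_cytoplasm",
    "gen_traits",
    "simulate_dataset",
    "write_simulated_dataset",
    "fixture_table1",
]


@dataclass(frozen=True)
class SimSpec:
    """Generator settings.

    Defaults emulate a two-population panel at the scale the recovery
    studies use: 50 accessions per population, 100 dominant + 20 codominant
    loci, moderate drift (F = 0.05), pure (non-admixed) ancestry.
    """

    K_true: int = 2
    n_per_pop: tuple[int, ...] = (50, 50)
    n_dominant: int = 100
    n_codominant: int = 20
    alleles_per_ssr: tuple[int, int] = (7, 17)  # surveyed SSR allele range
    drift_F: float | tuple[float, ...] = 0.05
    admixture_alpha: float | None = None  # None => pure populations
    cytoplasm_map: tuple[str, ...] | None = None  # per-population type
    cytoplasm_mixing_rate: float = 0.0
    seed_class_map: tuple[str, ...] | None = None  # per-population large/small
    seed_length_params: dict = field(
        default_factory=lambda: {"large": (11.0, 1.0), "small": (6.0, 1.0)}
    )
    trait_corr: float = 0.823  # target seed-length/fruit-weight correlation
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise DataError("K_true must be >= 1")
        if len(self.n_per_pop) != self.K_true:
            raise DataError("n_per_pop must have K_true entries")
        if any(n <= 0 for n in self.n_per_pop):
            raise DataError("population sizes must be positive")
        if self.n_dominant + self.n_codominant == 0:
            raise DataError("need at least one locus")
        for f in self.drift_vector():
            if not 0.0 < f < 0.5:
                raise DataError(f"drift F must lie in (0, 0.5), got {f}")
        lm, ls = self.seed_length_params["large"], self.seed_length_params["small"]
        if not (lm[0] >= SEED_LENGTH_CUT_MM > ls[0]):
            raise DataError(
                "seed-length class means must straddle the "
                f"{SEED_LENGTH_CUT_MM} mm cut"
            )

    def drift_vector(self) -> tuple[float, ...]:
        if isinstance(self.drift_F, (int, float)):
            return (float(self.drift_F),) * self.K_true
        if len(self.drift_F) != self.K_true:
            raise DataError("drift_F must be scalar or have K_true entries")
        return tuple(float(f) for f in self.drift_F)

    def cytoplasm_vector(self) -> tuple[str, ...]:
        if self.cytoplasm_map is not None:
            if len(self.cytoplasm_map) != self.K_true:
                raise DataError("cytoplasm_map must have K_true entries")
            return tuple(self.cytoplasm_map)
        return tuple(
            CYTOPLASM_TYPES[k % len(CYTOPLASM_TYPES)] for k in range(self.K_true)
        )

    def seed_class_vector(self) -> tuple[str, ...]:
        if self.seed_class_map is not None:
            if len(self.seed_class_map) != self.K_true:
                raise DataError("seed_class_map must have K_true entries")
            return tuple(self.seed_class_map)
        # alternate, small first (odd-K panels keep both classes present)
        return tuple("small" if k % 2 == 0 else "large" for k in range(self.K_true))


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    Q: np.ndarray  # (N, K) true admixture proportions
    population: np.ndarray  # (N,) majority-ancestry population index
    ancestral_freqs: list[np.ndarray]  # per locus
    pop_freqs: list[np.ndarray]  # per locus, (K, n_alleles)
    cytoplasm_type: pd.Series | None = None
    seed_class: pd.Series | None = None


@dataclass
class SimulatedDataset:
    spec: SimSpec
    genotypes: GenotypeMatrix
    truth: SimTruth
    caps_calls: pd.DataFrame | None = None
    cytoplasm_key: CytoplasmKey | None = None
    traits: pd.DataFrame | None = None
    metadata: list[AccessionRecord] | None = None


def _rng_for(spec: SimSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.master_seed, stage]))


def gen_admixed_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw genotypes under the correlated allele-frequency model."""
    rng = _rng_for(spec, 1)
    K = spec.K_true
    N = int(sum(spec.n_per_pop))
    drift = np.array(spec.drift_vector())
    ratio = (1.0 - drift) / drift  # per-population Dirichlet scale

    # true admixture proportions
    if spec.admixture_alpha is None:
        q = np.zeros((N, K))
        start = 0
        for k, n in enumerate(spec.n_per_pop):
            q[start : start + n, k] = 1.0
            start += n
    else:
        q = rng.dirichlet(np.full(K, float(spec.admixture_alpha)), size=N)
    population = q.argmax(axis=1)

    accessions = [f"ACC{i + 1:03d}" for i in range(N)]
    markers: list[MarkerDef] = []
    ancestral: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []
    calls = np.zeros((N, spec.n_dominant + spec.n_codominant, 2), dtype=np.int64)

    # dominant loci: two-state band frequencies, recorded as 1/1 or 0/0
    for l in range(spec.n_dominant):
        markers.append(MarkerDef(f"R{l + 1:03d}", "dominant"))
        pa = rng.beta(1.0, 1.0)
        pa = float(np.clip(pa, 0.02, 0.98))
        pk = rng.beta(pa * ratio, (1.0 - pa) * ratio)  # (K,)
        ancestral.append(np.array([1.0 - pa, pa]))
        pop_freqs.append(np.column_stack([1.0 - pk, pk]))
        origin = _sample_categorical(rng, q)  # one effective draw per accession
        band = rng.random(N) < pk[origin]
        calls[:, l, 0] = band.astype(np.int64)
        calls[:, l, 1] = band.astype(np.int64)

    # codominant loci: two independent allele draws from the Q-mixture
    lo, hi = spec.alleles_per_ssr
    for c in range(spec.n_codominant):
        j = int(rng.integers(lo, hi + 1))
        labels = tuple(str(a + 1) for a in range(j))
        markers.append(MarkerDef(f"S{c + 1:02d}", "codominant", allele_labels=labels))
        pa = rng.dirichlet(np.ones(j))
        pk = np.vstack([rng.dirichlet(pa * r) for r in ratio])  # (K, j)
        ancestral.append(pa)
        pop_freqs.append(pk)
        l = spec.n_dominant + c
        pair = np.empty((N, 2), dtype=np.int64)
        for copy in range(2):
            origin = _sample_categorical(rng, q)
            cum = np.cumsum(pk[origin], axis=1)
            u = rng.random(N) * cum[:, -1]
            pair[:, copy] = (cum < u[:, None]).sum(axis=1)
        pair.sort(axis=1)
        calls[:, l, :] = pair + 1  # size ranks are 1-based

    g = GenotypeMatrix(accessions, markers, calls)
    truth = SimTruth(
        Q=q, population=population, ancestral_freqs=ancestral, pop_freqs=pop_freqs
    )
    return g, truth


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return np.minimum((cum < u[:, None]).sum(axis=1), probs.shape[1] - 1)


# three diagnostic CAPS markers; the letter tuples form a substitution ladder
_CAPS_MARKERS = ("Cp01", "Cp02", "Cp03")
_TYPE_HAPLOTYPES = {
    "Ia": ("A", "A", "A"),
    "Ib": ("B", "A", "A"),
    "Ic": ("B", "B", "A"),
    "III": ("B", "B", "B"),
}
_LETTER_PATTERNS = {"A": "cut", "B": "uncut"}


def gen_cytoplasm(
    truth: SimTruth, spec: SimSpec, accessions: Sequence[str]
) -> tuple[pd.DataFrame, CytoplasmKey]:
    """Emit CAPS pattern calls and a matching key.

    The maternal lineage follows the majority-ancestry population
    deterministically (via ``spec.cytoplasm_map``); a nonzero
    ``cytoplasm_mixing_rate`` reassigns that fraction of accessions to a
    random other type.
    """
    rng = _rng_for(spec, 2)
    type_by_pop = spec.cytoplasm_vector()
    types = [type_by_pop[k] for k in truth.population]
    if spec.cytoplasm_mixing_rate > 0:
        for i in range(len(types)):
            if rng.random() < spec.cytoplasm_mixing_rate:
                others = [t for t in CYTOPLASM_TYPES if t != types[i]]
                types[i] = others[int(rng.integers(len(others)))]
    key = CytoplasmKey(
        markers=list(_CAPS_MARKERS),
        pattern_map={
            mk: {pat: letter for letter, pat in _LETTER_PATTERNS.items()}
            for mk in _CAPS_MARKERS
        },
        type_map={h: t for t, h in _TYPE_HAPLOTYPES.items()},
    )
    rows = {}
    for acc, t in zip(accessions, types):
        letters = _TYPE_HAPLOTYPES[t]
        rows[acc] = {
            mk: _LETTER_PATTERNS[letter]
            for mk, letter in zip(_CAPS_MARKERS, letters)
        }
    calls = pd.DataFrame.from_dict(rows, orient="index")
    calls = calls.loc[list(accessions), list(_CAPS_MARKERS)]
    truth.cytoplasm_type = pd.Series(types, index=list(accessions), name="cytoplasm_type")
    return calls, key


# per-class mean profiles for the non-seed traits (units as surveyed:
# cm for lengths, g for fruit weight, arbitrary ordinal scores otherwise)
_CLASS_TRAIT_MEANS = {
    "large": {
        "leaf_length": 14.0,
        "leaf_width": 16.0,
        "petiole_length": 9.0,
        "internode_length": 12.0,
        "fruit_length": 20.0,
        "fruit_diameter": 12.0,
        "flesh_thickness": 3.0,
        "flesh_color": 3.0,
        "exocarp_color": 3.0,
        "exocarp_dots": 1.5,
        "fruit_groove": 1.5,
        "brix": 8.0,
    },
    "small": {
        "leaf_length": 10.0,
        "leaf_width": 11.0,
        "petiole_length": 6.0,
        "internode_length": 8.0,
        "fruit_length": 8.0,
        "fruit_diameter": 6.0,
        "flesh_thickness": 1.2,
        "flesh_color": 1.5,
        "exocarp_color": 2.0,
        "exocarp_dots": 0.5,
        "fruit_groove": 0.5,
        "brix": 4.0,
    },
}
_FLOWER_PROBS = {"large": (0.2, 0.2, 0.6), "small": (0.5, 0.2, 0.3)}
_FRUIT_WEIGHT_LOC, _FRUIT_WEIGHT_SCALE = 500.0, 450.0


def gen_traits(
    truth: SimTruth, spec: SimSpec, accessions: Sequence[str]
) -> tuple[pd.DataFrame, list[AccessionRecord]]:
    """Emit the 16-trait table and accession metadata.

    Seed lengths are Gaussian per class (truncated positive); fruit weight
    is built from the standardized seed length so that their sample
    correlation targets ``spec.trait_corr``; the remaining traits are
    Gaussian around class-specific means.
    """
    rng = _rng_for(spec, 3)
    classes = [spec.seed_class_vector()[k] for k in truth.population]
    n = len(accessions)

    length = np.empty(n)
    for i, cls in enumerate(classes):
        mu, sd = spec.seed_length_params[cls]
        val = rng.normal(mu, sd)
        while val <= 0.5:  # truncate away nonphysical draws
            val = rng.normal(mu, sd)
        length[i] = val
    z = (length - length.mean()) / length.std(ddof=0)
    rho = float(spec.trait_corr)
    w_std = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=n)
    weight = np.maximum(_FRUIT_WEIGHT_LOC + _FRUIT_WEIGHT_SCALE * w_std, 5.0)

    width = np.maximum(0.35 * length + rng.normal(0.0, 0.3, size=n), 0.5)
    flower = np.array(
        [
            rng.choice([0, 1, 2], p=_FLOWER_PROBS[cls])
            for cls in classes
        ],
        dtype=float,
    )

    data = {
        "seed_length": length,
        "seed_width": width,
        "flower_type": flower,
        "fruit_weight": weight,
    }
    for trait in TRAIT_NAMES:
        if trait in data:
            continue
        mus = np.array([_CLASS_TRAIT_MEANS[cls][trait] for cls in classes])
        sd = 0.15 * np.abs(mus).mean() + 0.1
        data[trait] = np.maximum(mus + rng.normal(0.0, sd, size=n), 0.0)
    table = pd.DataFrame(data, index=list(accessions))[TRAIT_NAMES]

    meta = [
        AccessionRecord(
            id=str(acc),
            region_group=f"Pop{truth.population[i] + 1}",
            seed_length_mm=float(length[i]),
            seed_width_mm=float(width[i]),
        )
        for i, acc in enumerate(accessions)
    ]
    truth.seed_class = pd.Series(classes, index=list(accessions), name="seed_class")
    return table, meta


def simulate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Run all generator stages; fully deterministic from ``master_seed``."""
    g, truth = gen_admixed_genotypes(spec)
    calls, key = gen_cytoplasm(truth, spec, g.accessions)
    traits, meta = gen_traits(truth, spec, g.accessions)
    return SimulatedDataset(
        spec=spec,
        genotypes=g,
        truth=truth,
        caps_calls=calls,
        cytoplasm_key=key,
        traits=traits,
        metadata=meta,
    )


def write_simulated_dataset(data: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV/YAML files the pipeline consumes; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "panel": outdir / "panel.tsv",
        "metadata": outdir / "metadata.tsv",
        "traits": outdir / "traits.tsv",
        "caps_calls": outdir / "caps_calls.tsv",
        "cytoplasm_key": outdir / "cytoplasm_key.yaml",
    }
    write_genotype_matrix(data.genotypes, paths["genotypes"])
    panel_rows = []
    for mk in data.genotypes.markers:
        panel_rows.append(
            {
                "marker": mk.name,
                "kind": mk.kind,
                "chromosome": mk.chromosome or "",
                "alleles": ",".join(mk.allele_labels),
            }
        )
    pd.DataFrame(panel_rows).to_csv(paths["panel"], sep="\t", index=False)
    assert data.metadata is not None and data.traits is not None
    pd.DataFrame(
        [
            {
                "accession": r.id,
                "region_group": r.region_group,
                "seed_length_mm": r.seed_length_mm,
                "seed_width_mm": r.seed_width_mm,
                "horticultural_group": r.horticultural_group or "",
            }
            for r in data.metadata
        ]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    data.traits.rename_axis("accession").to_csv(paths["traits"], sep="\t")
    assert data.caps_calls is not None and data.cytoplasm_key is not None
    data.caps_calls.rename_axis("accession").to_csv(paths["caps_calls"], sep="\t")
    data.cytoplasm_key.to_yaml(paths["cytoplasm_key"])
    return paths


def fixture_table1() -> ContingencyTable:
    """Seed-size counts of the four African geographical groups (97 accessions)."""
    return ContingencyTable(
        row_labels=["Northern Africa", "Sudan", "Western Africa", "Southern Africa"],
        col_labels=["large", "small"],
        counts=np.array([[37, 1], [17, 21], [2, 10], [1, 8]]),
    )
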