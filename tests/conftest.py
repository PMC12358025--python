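import numpy as np
import pytest

from melodiv.data_model import Genotype, GenotypeMatrix, MarkerDef


def make_matrix(tokens: dict[str, list[str]], kinds: dict[str, str],
                accessions: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker: [token per accession]}."""
    markers = []
    for name, kind in kinds.items():
        labels = ()
        if kind == "codominant":
            alleles = set()
            for tok in tokens[name]:
                if tok != ".":
                    alleles.update(int(x) for x in tok.split("/"))
            labels = tuple(str(a) for a in sorted(alleles))
        markers.append(MarkerDef(name, kind, allele_labels=labels))
    n = len(next(iter(tokens.values())))
    if accessions is None:
        accessions = [f"A{i + 1}" for i in range(n)]
    calls = np.full((n, len(markers), 2), -1, dtype=np.int64)
    for j, mk in enumerate(markers):
        for i, tok in enumerate(tokens[mk.name]):
            gt = Genotype.from_token(tok, mk.kind)
            if not gt.missing:
                calls[i, j] = (gt.allele_a, gt.allele_b)
    return GenotypeMatrix(accessions, markers, calls)


@pytest.fixture
def tiny_mixed_matrix() -> GenotypeMatrix:
    """4 accessions x (2 RAPD + 2 SSR)."""
    return make_matrix(
        {
            "R1": ["1/1", "1/1", "0/0", "0/0"],
            "R2": ["1/1", "0/0", "1/1", "0/0"],
            "S1": ["2/2", "2/3", "3/3", "2/3"],
            "S2": ["1/1", "1/2", "2/2", "1/1"],
        },
        {"R1": "dominant", "R2": "dominant", "S1": "codominant", "S2": "codominant"},
    )
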