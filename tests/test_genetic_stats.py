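"""Band-sharing similarity, diversity statistics, and the chi-square test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melodiv.data_model import DataError, Genotype
from melodiv.genetic_stats import (
    ContingencyTable,
    allele_freqs,
    chi_square_independence,
    gd_matrix,
    gene_diversity,
    gs_components,
    gs_matrix,
    gs_pair,
    marker_share,
    nei_distance_1972,
    pic,
)
from melodiv.simulate import SimSpec, gen_admixed_genotypes

from conftest import make_matrix


def tok(s: str, kind: str = "codominant") -> Genotype:
    return Genotype.from_token(s, kind)


class TestMarkerShare:
    @pytest.mark.parametrize(
        "a,b,score,channel",
        [
            ("1/1", "1/1", 1.0, "positive"),
            ("0/0", "0/0", 1.0, "null"),
            ("1/1", "0/0", 0.0, "mismatch"),
        ],
    )
    def test_dominant_channels(self, a, b, score, channel):
        res = marker_share(tok(a, "dominant"), tok(b, "dominant"), "dominant")
        assert (res.score, res.channel) == (score, channel)

    @pytest.mark.parametrize(
        "a,b,score",
        [
            ("2/2", "2/3", 0.5),  # the worked heterozygote case
            ("2/3", "2/3", 1.0),
            ("2/3", "2/4", 0.5),
            ("2/2", "3/3", 0.0),
            ("2/3", "4/5", 0.0),
            ("2/2", "2/2", 1.0),
        ],
    )
    def test_codominant_set_rule(self, a, b, score):
        res = marker_share(tok(a), tok(b), "codominant")
        assert res.score == pytest.approx(score)
        assert res.channel == ("positive" if score > 0 else "mismatch")

    def test_share_is_symmetric(self):
        for a, b in [("2/2", "2/3"), ("2/3", "2/4"), ("1/1", "0/0")]:
            kind = "dominant" if a in ("1/1", "0/0") else "codominant"
            assert marker_share(tok(a, kind), tok(b, kind), kind).score == \
                marker_share(tok(b, kind), tok(a, kind), kind).score

    def test_missing_excluded(self):
        res = marker_share(tok("."), tok("2/2"), "codominant")
        assert res.channel == "excluded"


def _nineteen_marker_pair():
    """12 RAPD (6 both-present, 3 both-absent, 3 mismatched) +
    7 SSR (4 identical, 2 half-shared, 1 disjoint)."""
    tokens = {}
    kinds = {}
    a_row = (["1/1"] * 6 + ["0/0"] * 3 + ["1/1"] * 3,
             ["2/2"] * 4 + ["2/2", "3/3"] + ["1/1"])
    b_row = (["1/1"] * 6 + ["0/0"] * 3 + ["0/0"] * 3,
             ["2/2"] * 4 + ["2/3", "3/4"] + ["2/2"])
    for i in range(12):
        name = f"R{i + 1}"
        kinds[name] = "dominant"
        tokens[name] = [a_row[0][i], b_row[0][i]]
    for i in range(7):
        name = f"S{i + 1}"
        kinds[name] = "codominant"
        tokens[name] = [a_row[1][i], b_row[1][i]]
    return make_matrix(tokens, kinds, ["X", "Y"])


class TestGsPair:
    def test_identical_accessions_gs_one(self, tiny_mixed_matrix):
        assert gs_pair(tiny_mixed_matrix, 0, 0) == pytest.approx(1.0)

    def test_hand_counted_nineteen_marker_example(self):
        g = _nineteen_marker_pair()
        comp = gs_components(g, "X", "Y")
        assert comp.n_markers == 19
        assert comp.n00 == 3
        assert comp.n11 == pytest.approx(6 + 4 + 2 * 0.5)
        assert gs_pair(g, "X", "Y") == pytest.approx(14 / 19)

    def test_all_mismatched_gs_zero(self):
        g = make_matrix(
            {"R1": ["1/1", "0/0"], "S1": ["2/2", "3/3"]},
            {"R1": "dominant", "S1": "codominant"},
        )
        assert gs_pair(g, 0, 1) == pytest.approx(0.0)

    def test_pairwise_deletion_denominator(self):
        g = make_matrix(
            {"R1": ["1/1", "1/1"], "R2": [".", "0/0"], "S1": ["2/2", "2/2"]},
            {"R1": "dominant", "R2": "dominant", "S1": "codominant"},
        )
        comp = gs_components(g, 0, 1)
        assert comp.n_markers == 2  # R2 excluded pairwise
        assert gs_pair(g, 0, 1) == pytest.approx(1.0)

    def test_no_shared_markers_errors(self):
        g = make_matrix(
            {"R1": ["1/1", "."], "R2": [".", "0/0"]},
            {"R1": "dominant", "R2": "dominant"},
        )
        with pytest.raises(DataError, match="non-missing"):
            gs_pair(g, 0, 1)


class TestGdMatrix:
    def test_duplicate_accessions_distance_zero(self):
        g = make_matrix(
            {"R1": ["1/1", "1/1"], "S1": ["2/3", "2/3"]},
            {"R1": "dominant", "S1": "codominant"},
        )
        d = gd_matrix(g)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_complement_of_gs(self):
        g = _nineteen_marker_pair()
        d = gd_matrix(g)
        assert d.values[0, 1] == pytest.approx(1 - 14 / 19)

    def test_shape_symmetry_bounds(self, tiny_mixed_matrix):
        d = gd_matrix(tiny_mixed_matrix)
        n = tiny_mixed_matrix.n_accessions
        assert d.values.shape == (n, n)
        assert np.allclose(d.values, d.values.T)
        assert np.all((d.values >= 0) & (d.values <= 1))
        assert np.allclose(np.diag(d.values), 0)

    def test_matches_per_pair_recount(self):
        """Vectorized GS equals the scalar per-marker recount (oracle)."""
        g, _ = gen_admixed_genotypes(
            SimSpec(n_per_pop=(6, 6), n_dominant=8, n_codominant=4, master_seed=5)
        )
        gs = gs_matrix(g)
        for i in range(0, g.n_accessions, 3):
            for j in range(i + 1, g.n_accessions, 3):
                assert gs.iloc[i, j] == pytest.approx(gs_pair(g, i, j))


class TestAlleleFreqs:
    def test_codominant_gene_copy_counting(self):
        g = make_matrix({"S1": ["2/3", "2/3"]}, {"S1": "codominant"})
        table = allele_freqs(g)
        vec = table.vector("all", "S1")
        assert vec.loc[2] == pytest.approx(0.5)
        assert vec.loc[3] == pytest.approx(0.5)

    def test_dominant_band_frequency(self):
        g = make_matrix({"R1": ["1/1", "1/1", "1/1", "0/0"]}, {"R1": "dominant"})
        vec = allele_freqs(g).vector("all", "R1")
        assert vec.loc[1] == pytest.approx(0.75)

    def test_frequencies_sum_to_one(self, tiny_mixed_matrix):
        table = allele_freqs(
            tiny_mixed_matrix, {a: ("G1" if i < 2 else "G2")
                                for i, a in enumerate(tiny_mixed_matrix.accessions)}
        )
        for grp in table.groups:
            for mk in table.freqs[grp]:
                assert table.vector(grp, mk).sum() == pytest.approx(1.0, abs=1e-9)


class TestPic:
    def test_dominant_maximum_at_half(self):
        assert pic([0.5, 0.5], "dominant") == pytest.approx(0.5)

    def test_codominant_biallelic_value(self):
        # 1 - 0.5 - 2 * (0.25 * 0.25)
        assert pic([0.5, 0.5], "codominant") == pytest.approx(0.375)

    def test_monomorphic_zero(self):
        assert pic([1.0], "codominant") == pytest.approx(0.0)
        assert pic([1.0], "dominant") == pytest.approx(0.0)

    def test_empty_vector_errors(self):
        with pytest.raises(DataError):
            pic([], "codominant")

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_codominant_bounded_by_gene_diversity(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = 1 - np.sum(p**2)
        assert pic(p, "codominant") <= h + 1e-12

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_dominant_maximized_at_half(self, p):
        assert pic([1 - p, p], "dominant") <= 0.5 + 1e-12


class TestGeneDiversity:
    def _table(self, vectors):
        import pandas as pd

        from melodiv.genetic_stats import AlleleFreqTable

        freqs = {"G": {f"M{i}": pd.Series(v, index=range(len(v)))
                       for i, v in enumerate(vectors)}}
        return AlleleFreqTable(freqs=freqs, sample_sizes={"G": 10})

    def test_monomorphic_zero(self):
        assert gene_diversity(self._table([[1.0], [1.0]]), "G") == pytest.approx(0.0)

    def test_two_locus_average(self):
        t = self._table([[0.5, 0.5], [1.0]])
        assert gene_diversity(t, "G") == pytest.approx(0.25)

    def test_three_allele_locus(self):
        t = self._table([[0.5, 0.25, 0.25]])
        assert gene_diversity(t, "G") == pytest.approx(0.625)

    def test_unknown_group_errors(self):
        with pytest.raises(DataError):
            gene_diversity(self._table([[1.0]]), "nope")


class TestNeiDistance:
    def _table(self, a_vecs, b_vecs):
        import pandas as pd

        from melodiv.genetic_stats import AlleleFreqTable

        freqs = {
            "A": {f"M{i}": pd.Series(v, index=range(len(v))) for i, v in enumerate(a_vecs)},
            "B": {f"M{i}": pd.Series(v, index=range(len(v))) for i, v in enumerate(b_vecs)},
        }
        return AlleleFreqTable(freqs=freqs, sample_sizes={"A": 10, "B": 10})

    def test_identical_profiles_zero(self):
        t = self._table([[0.3, 0.7]], [[0.3, 0.7]])
        assert nei_distance_1972(t, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_single_locus_hand_value(self):
        t = self._table([[1.0, 0.0]], [[0.5, 0.5]])
        # I = 0.5 / sqrt(1 * 0.5), D = -ln I
        assert nei_distance_1972(t, "A", "B") == pytest.approx(0.5 * math.log(2))

    def test_disjoint_alleles_infinite(self):
        t = self._table([[1.0, 0.0]], [[0.0, 1.0]])
        assert math.isinf(nei_distance_1972(t, "A", "B"))

    def test_monotone_along_interpolation(self):
        p = np.array([0.8, 0.2])
        q = np.array([0.2, 0.8])
        prev = -1.0
        for lam in np.linspace(0.0, 1.0, 6):
            mix = (1 - lam) * p + lam * q
            t = self._table([p.tolist()], [mix.tolist()])
            d = nei_distance_1972(t, "A", "B")
            assert d > prev - 1e-12
            prev = d


class TestChiSquare:
    def test_uniform_table_zero(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.array([[5, 5], [5, 5]]))
        res = chi_square_independence(t)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_diagonal_table(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 0], [0, 10]]))
        res = chi_square_independence(t)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_zero_margin_errors(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], np.array([[0, 0], [5, 5]]))
        with pytest.raises(DataError):
            chi_square_independence(t)

    def test_matches_textbook_formula_on_random_tables(self):
        """Oracle: direct Pearson sum over 20 random tables."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 40, size=(r, c))
            t = ContingencyTable([f"r{i}" for i in range(r)],
                                 [f"c{j}" for j in range(c)], counts)
            res = chi_square_independence(t)
            total = counts.sum()
            expected = np.outer(counts.sum(1), counts.sum(0)) / total
            stat = ((counts - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat)
            assert res.df == (r - 1) * (c - 1)
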