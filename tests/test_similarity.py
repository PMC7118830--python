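"""Similarity kernels: edit distance, Wang measure, GIP, integration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from circimc import (
    AssociationDataset,
    EditCosts,
    OntologyGraph,
    SequenceRecord,
    edit_distance,
    gip_similarity_matrix,
    integrate_similarity,
    sequence_similarity,
    sequence_similarity_matrix,
    wang_contributions,
    wang_similarity,
    wang_similarity_matrix,
)
from circimc.similarity import SimilarityMatrix, gip_bandwidth

dna = st.text(alphabet="ACGT", max_size=8)


def _lcs(a: str, b: str) -> int:
    """Brute-force longest common subsequence length (independent oracle)."""
    L = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i, ca in enumerate(a, 1):
        for j, cb in enumerate(b, 1):
            L[i][j] = L[i - 1][j - 1] + 1 if ca == cb else max(L[i - 1][j], L[i][j - 1])
    return L[len(a)][len(b)]


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("A", "T", 2.0),   # substitution costs the same as delete+insert
            ("AC", "A", 1.0),  # single deletion
            ("", "ACG", 3.0),
            ("ACG", "", 3.0),
        ],
    )
    def test_hand_computed_distances(self, a, b, expected):
        assert edit_distance(a, b) == expected

    @given(dna, dna)
    def test_matches_lcs_identity(self, a, b):
        """With costs (1,1,2) the distance is len_a + len_b - 2*LCS."""
        assert edit_distance(a, b) == len(a) + len(b) - 2 * _lcs(a, b)

    def test_asymmetric_costs(self):
        costs = EditCosts(insertion=3.0, deletion=1.0, substitution=10.0)
        assert edit_distance("AA", "", costs) == 2.0
        assert edit_distance("", "AA", costs) == 6.0
        # substitution so dear that delete+insert wins
        assert edit_distance("A", "T", costs) == 4.0

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            EditCosts(insertion=-1)


class TestSequenceSimilarity:
    def test_identical_sequences(self):
        assert sequence_similarity("ACGT", "ACGT") == 1.0

    def test_fully_distinct_single_bases(self):
        assert sequence_similarity("A", "T") == 0.0

    def test_single_deletion(self):
        assert sequence_similarity("AC", "A") == pytest.approx(2 / 3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_similarity("", "A")

    def test_matrix_matches_pairwise_calls(self, toy_records):
        sim = sequence_similarity_matrix(toy_records)
        for i, a in enumerate(toy_records):
            for j, b in enumerate(toy_records):
                assert sim.S[i, j] == pytest.approx(
                    1.0 if i == j else sequence_similarity(a.sequence, b.sequence)
                )

    def test_matrix_single_record(self):
        sim = sequence_similarity_matrix([SequenceRecord("c1", "ACGT")])
        assert sim.S.tolist() == [[1.0]]

    def test_matrix_identical_sequences_offdiag_one(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        assert sequence_similarity_matrix(recs).S[0, 1] == 1.0

    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("a", "ACGA")]
        with pytest.raises(ValueError):
            sequence_similarity_matrix(recs)


class TestWangMeasure:
    def test_root_contributes_only_itself(self):
        ont = OntologyGraph({"r": set()})
        assert wang_contributions(ont, "r") == {"r": 1.0}

    def test_chain_decay(self, chain_ontology):
        s = wang_contributions(chain_ontology, "a")
        assert s == pytest.approx({"a": 1.0, "b": 0.7, "c": 0.49})

    def test_diamond_max_over_paths(self, diamond_ontology):
        s = wang_contributions(diamond_ontology, "a")
        assert s["r"] == pytest.approx(0.49)

    def test_missing_term_errors(self, chain_ontology):
        with pytest.raises(KeyError):
            wang_contributions(chain_ontology, "zzz")

    def test_self_similarity_is_one(self, chain_ontology):
        assert wang_similarity(chain_ontology, "a", "a") == pytest.approx(1.0)

    def test_sibling_similarity(self, sibling_ontology):
        expected = (0.7 + 0.7) / (1.7 + 1.7)
        assert wang_similarity(sibling_ontology, "a", "b") == pytest.approx(expected)
        assert expected == pytest.approx(0.4118, abs=1e-4)

    def test_disconnected_terms_zero(self):
        ont = OntologyGraph({"a": set(), "b": set()})
        assert wang_similarity(ont, "a", "b") == 0.0

    def test_symmetry(self, diamond_ontology):
        for x, y in [("a", "b"), ("a", "r"), ("b", "c")]:
            assert wang_similarity(diamond_ontology, x, y) == pytest.approx(
                wang_similarity(diamond_ontology, y, x)
            )

    def test_matrix_matches_pairwise(self, diamond_ontology):
        terms = ["a", "b", "c", "r"]
        sim = wang_similarity_matrix(diamond_ontology, terms)
        for i, x in enumerate(terms):
            for j, y in enumerate(terms):
                assert sim.S[i, j] == pytest.approx(
                    wang_similarity(diamond_ontology, x, y)
                )

    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValueError, match="DAG"):
            OntologyGraph({"a": {"b"}, "b": {"a"}})


class TestGIP:
    def test_bandwidth_one_association_per_row(self, toy_dataset):
        ds = AssociationDataset(["c1", "c2"], ["d1", "d2"], np.eye(2))
        assert gip_bandwidth(ds, "rows") == 1.0

    def test_bandwidth_hand_computed(self):
        ds = AssociationDataset(["c1", "c2"], ["d1", "d2"], [[1, 1], [0, 1]])
        assert gip_bandwidth(ds, "rows") == pytest.approx(2 / 3)

    def test_bandwidth_zero_matrix_errors(self):
        ds = AssociationDataset(["c1"], ["d1"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            gip_bandwidth(ds, "rows")

    def test_identity_profiles_similarity_one(self):
        ds = AssociationDataset(["c1", "c2"], ["d1"], [[1], [1]])
        assert gip_similarity_matrix(ds, "rows").S[0, 1] == pytest.approx(1.0)

    def test_identity_matrix_off_diagonal(self):
        ds = AssociationDataset(["c1", "c2"], ["d1", "d2"], np.eye(2))
        sim = gip_similarity_matrix(ds, "rows")
        assert sim.S[0, 1] == pytest.approx(np.exp(-2))
        assert sim.S[0, 0] == 1.0

    def test_entries_positive_and_bounded(self, planted):
        for axis in ("rows", "columns"):
            S = gip_similarity_matrix(planted.dataset, axis).S
            assert (S > 0).all() and (S <= 1).all()

    def test_decreases_with_hamming_distance(self):
        # profiles at Hamming distance 1, 2, 3 from row 0, fixed bandwidth
        A = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 0],
                [1, 0, 0, 0, 0, 0],
                [0, 0, 0, 1, 0, 0],
            ]
        )
        ds = AssociationDataset([f"c{i}" for i in range(4)],
                                [f"d{j}" for j in range(6)], A)
        S = gip_similarity_matrix(ds, "rows").S
        assert S[0, 1] > S[0, 2] > S[0, 3]


class TestIntegration:
    def _pair(self):
        ids = ["x", "y"]
        a = SimilarityMatrix(ids, [[1.0, 0.4], [0.4, 1.0]])
        b = SimilarityMatrix(ids, [[1.0, 0.8], [0.8, 1.0]])
        return a, b

    def test_equal_weights_average(self):
        a, b = self._pair()
        assert integrate_similarity(a, b, 0.5).S[0, 1] == pytest.approx(0.6)

    def test_weight_extremes(self):
        a, b = self._pair()
        assert integrate_similarity(a, b, 1.0).S[0, 1] == pytest.approx(0.4)
        assert integrate_similarity(a, b, 0.0).S[0, 1] == pytest.approx(0.8)

    def test_id_mismatch_rejected(self):
        a, _ = self._pair()
        c = SimilarityMatrix(["x", "z"], np.eye(2))
        with pytest.raises(ValueError):
            integrate_similarity(a, c)

    @given(st.integers(0, 2**31 - 1), st.floats(0, 1))
    def test_preserves_similarity_invariants(self, seed, weight):
        """Any convex mix of valid kernels is symmetric, unit-diagonal, in [0,1]."""
        rng = np.random.default_rng(seed)
        n = 4
        X = rng.random((n, n))
        ids = [f"e{i}" for i in range(n)]
        mats = []
        for _ in range(2):
            X = rng.random((n, n))
            S = (X + X.T) / 2
            np.fill_diagonal(S, 1.0)
            mats.append(SimilarityMatrix(ids, S))
        out = integrate_similarity(mats[0], mats[1], weight)
        assert np.allclose(out.S, out.S.T)
        assert np.allclose(np.diag(out.S), 1.0)
        assert out.S.min() >= 0 and out.S.max() <= 1


@pytest.mark.parametrize("kind", ["sequence", "wang", "gip"])
def test_all_kernels_are_valid_similarity_matrices(kind, planted):
    """Symmetry, unit diagonal and [0,1] range hold on realistic inputs."""
    if kind == "sequence":
        sim = sequence_similarity_matrix(planted.sequences[:12])
    elif kind == "wang":
        sim = wang_similarity_matrix(
            planted.ontology, list(planted.dataset.disease_ids)
        )
    else:
        sim = gip_similarity_matrix(planted.dataset, "rows")
    S = sim.S
    assert np.array_equal(S, S.T)
    assert np.all(np.diag(S) == 1.0)
    assert S.min() >= 0 and S.max() <= 1
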