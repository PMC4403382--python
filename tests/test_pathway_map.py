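"""Oncoprint matrices, exclusivity, correlation and RF+PAM clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from somascape.io_cohort import MutationCatalog
from somascape.pathway_map import (AlterationMatrix, PathwayDefinition,
                                   gene_alteration_matrix,
                                   mutual_exclusivity_test, pam,
                                   pathway_alteration_matrix,
                                   pathway_correlation, rf_pam_cluster)

from conftest import make_snv


@pytest.fixture
def small_matrix():
    roster = ["C1", "C2", "C3"]
    records = [
        make_snv("C1", "KRAS", "12", 100, "C", "A"),
        make_snv("C1", "TP53", "17", 200, "C", "T", vclass="silent"),
        make_snv("C2", "TP53", "17", 300, "C", "T"),
    ]
    catalog = MutationCatalog(records=records, case_roster=roster)
    calls = pd.DataFrame("neutral", index=roster,
                         columns=["KRAS", "TP53", "CDKN2A"])
    calls.loc["C3", "CDKN2A"] = "del"
    return gene_alteration_matrix(catalog, calls)


class TestGeneMatrix:
    def test_silent_only_is_zero(self, small_matrix):
        assert small_matrix.binary.loc["C1", "TP53"] == 0

    def test_deletion_only_counts(self, small_matrix):
        assert small_matrix.binary.loc["C3", "CDKN2A"] == 1

    def test_mutation_counts(self, small_matrix):
        assert small_matrix.binary.loc["C1", "KRAS"] == 1
        assert small_matrix.binary.loc["C2", "TP53"] == 1

    def test_empty_inputs_zero_matrix(self):
        catalog = MutationCatalog(records=[], case_roster=["C1", "C2"])
        calls = pd.DataFrame("neutral", index=["C1", "C2"], columns=["G"])
        m = gene_alteration_matrix(catalog, calls)
        assert (m.binary == 0).all().all()

    def test_roster_mismatch_error(self):
        catalog = MutationCatalog(records=[], case_roster=["C1"])
        calls = pd.DataFrame("neutral", index=["C1", "C2"], columns=["G"])
        with pytest.raises(ValueError, match="roster"):
            gene_alteration_matrix(catalog, calls)


class TestPathwayMatrix:
    def test_single_gene_pathway_equals_column(self, small_matrix):
        defs = [PathwayDefinition("P", {"KRAS": {"mutation"}})]
        mat, freqs = pathway_alteration_matrix(small_matrix, defs)
        assert (mat.binary["P"] == small_matrix.by_type["mutation"]["KRAS"]).all()
        assert freqs["P"] == pytest.approx(1 / 3)

    def test_union_of_disjoint_pathways_adds(self, small_matrix):
        defs = [PathwayDefinition("A", {"KRAS": {"mutation"}}),
                PathwayDefinition("B", {"CDKN2A": {"del"}}),
                PathwayDefinition("AB", {"KRAS": {"mutation"},
                                         "CDKN2A": {"del"}})]
        _, freqs = pathway_alteration_matrix(small_matrix, defs)
        assert freqs["AB"] == pytest.approx(freqs["A"] + freqs["B"])

    def test_pathway_dominates_member_columns(self, small_matrix):
        defs = [PathwayDefinition("P", {"KRAS": {"mutation"},
                                        "TP53": {"mutation"}})]
        mat, _ = pathway_alteration_matrix(small_matrix, defs)
        for g in ("KRAS", "TP53"):
            assert (mat.binary["P"] >=
                    small_matrix.by_type["mutation"][g]).all()

    def test_unknown_gene_skipped_with_warning(self, small_matrix):
        defs = [PathwayDefinition("P", {"KRAS": {"mutation"},
                                        "NOSUCH": {"mutation"}})]
        with pytest.warns(UserWarning, match="NOSUCH"):
            mat, _ = pathway_alteration_matrix(small_matrix, defs)
        assert mat.binary["P"].sum() == 1

    def test_pathway_empty_after_skipping_error(self, small_matrix):
        defs = [PathwayDefinition("P", {"NOSUCH": {"mutation"}})]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="usable"):
                pathway_alteration_matrix(small_matrix, defs)

    def test_qualifying_type_respected(self, small_matrix):
        # CDKN2A is deleted in C3; a mutation-only pathway must not see it
        defs = [PathwayDefinition("P", {"CDKN2A": {"mutation"}})]
        mat, _ = pathway_alteration_matrix(small_matrix, defs)
        assert mat.binary["P"].sum() == 0


class TestCorrelation:
    def test_identical_and_complementary_columns(self):
        df = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0],
                           "c": [0, 1, 0, 1]})
        corr = pathway_correlation(AlterationMatrix(binary=df))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_columns_excluded(self):
        df = pd.DataFrame({"a": [1, 0, 1], "b": [0, 1, 1],
                           "flat": [1, 1, 1]})
        with pytest.warns(UserWarning, match="flat"):
            corr = pathway_correlation(AlterationMatrix(binary=df))
        assert "flat" not in corr.columns

    def test_independent_generator_pathways_uncorrelated(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 2, size=(2000, 4)),
                          columns=list("abcd"))
        corr = pathway_correlation(AlterationMatrix(binary=df))
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)


class TestExclusivity:
    def _matrix(self, n, a_set, b_set):
        df = pd.DataFrame(0, index=[f"C{i}" for i in range(n)],
                          columns=["a", "b"])
        df.iloc[list(a_set), 0] = 1
        df.iloc[list(b_set), 1] = 1
        return AlterationMatrix(binary=df)

    def test_enumeration_example(self):
        # a in 50/109, b in 3/109, overlap 0: p = C(59,3)/C(109,3)
        m = self._matrix(109, range(50), range(50, 53))
        x, p = mutual_exclusivity_test(m, "a", "b")
        assert x == 0
        assert p == pytest.approx(math.comb(59, 3) / math.comb(109, 3))

    def test_absent_gene_b_gives_p_one(self):
        m = self._matrix(20, range(5), [])
        x, p = mutual_exclusivity_test(m, "a", "b")
        assert x == 0 and p == pytest.approx(1.0)

    def test_self_comparison_p_one(self):
        m = self._matrix(20, range(5), range(5))
        x, p = mutual_exclusivity_test(m, "a", "a")
        assert x == 5 and p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for n in (8, 12, 15):
            K = int(rng.integers(1, n))
            nb = int(rng.integers(1, n))
            a_set = set(rng.choice(n, K, replace=False).tolist())
            b_set = set(rng.choice(n, nb, replace=False).tolist())
            m = self._matrix(n, a_set, b_set)
            x, p = mutual_exclusivity_test(m, "a", "b")
            total = hits = 0
            for placement in itertools.combinations(range(n), nb):
                total += 1
                if len(a_set & set(placement)) <= x:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_missing_gene_error(self):
        m = self._matrix(10, range(2), range(2))
        with pytest.raises(KeyError):
            mutual_exclusivity_test(m, "a", "zzz")


class TestPAM:
    def test_hand_example_two_clusters(self):
        # points on a line: {0,1} and {10,11}
        x = np.array([0.0, 1.0, 10.0, 11.0])
        D = np.abs(x[:, None] - x[None, :])
        labels, medoids = pam(D, 2)
        assert len(set(labels[:2])) == 1 and len(set(labels[2:])) == 1
        assert labels[0] != labels[2]

    def test_k_equals_n(self):
        D = np.ones((3, 3)) - np.eye(3)
        labels, medoids = pam(D, 3)
        assert sorted(medoids) == [0, 1, 2]


class TestRFPam:
    def _blocks(self, n_per=8, seed=0):
        rng = np.random.default_rng(seed)
        a = np.tile([1, 1, 1, 0, 0, 0, 1, 0], (n_per, 1))
        b = np.tile([0, 0, 0, 1, 1, 1, 0, 1], (n_per, 1))
        df = pd.DataFrame(np.vstack([a, b]),
                          index=[f"C{i}" for i in range(2 * n_per)],
                          columns=[f"G{j}" for j in range(8)])
        return AlterationMatrix(binary=df)

    def test_recovers_duplicated_blocks(self):
        m = self._blocks()
        labels, D = rf_pam_cluster(m, k=2, n_trees=200, seed=1)
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_dissimilarity_properties(self):
        m = self._blocks()
        _, D = rf_pam_cluster(m, k=2, n_trees=100, seed=2)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0

    def test_deterministic_given_seed(self):
        m = self._blocks()
        l1, D1 = rf_pam_cluster(m, k=2, n_trees=100, seed=3)
        l2, D2 = rf_pam_cluster(m, k=2, n_trees=100, seed=3)
        assert np.array_equal(l1, l2) and np.allclose(D1, D2)

    def test_constant_matrix_error(self):
        df = pd.DataFrame(np.ones((10, 4), dtype=int))
        with pytest.raises(ValueError, match="constant"):
            rf_pam_cluster(AlterationMatrix(binary=df), k=2)
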