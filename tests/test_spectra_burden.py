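"""Spectrum classification, enrichment scores, burden and the
recurrence post-filter."""

import itertools
import math

import numpy as np
import pytest

from somascape import spectra_burden as sb
from somascape.io_cohort import MutationCatalog
from somascape.synth_cohort import builtin_signature, draw_contexts

from conftest import make_snv


class TestClassifySubstitution:
    def test_pyrimidine_reference_passthrough(self):
        assert sb.classify_substitution("C", "T", "ACG") == ("C>T", "A[C>T]G")

    def test_purine_reference_is_reverse_complemented(self):
        # G>T in context AGC collapses to C>A in context GCT
        assert sb.classify_substitution("G", "T", "AGC") == ("C>A", "G[C>A]T")

    def test_reverse_complement_involution(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            ctx = (str(rng.choice(list("ACGT"))) + ref
                   + str(rng.choice(list("ACGT"))))
            assert sb.classify_substitution(ref, alt, ctx) == \
                sb.classify_substitution(sb.revcomp(ref), sb.revcomp(alt),
                                         sb.revcomp(ctx))

    @pytest.mark.parametrize("ref,alt,ctx", [
        ("A", "A", "CAT"),       # ref == alt
        ("-", "A", "CAT"),       # indel
        ("C", "T", "CAT"),       # context centre mismatch
        ("C", "T", "AC"),        # short context
    ])
    def test_invalid_inputs(self, ref, alt, ctx):
        with pytest.raises(ValueError):
            sb.classify_substitution(ref, alt, ctx)


class TestCaseSpectrum:
    def test_single_mutation_point_mass(self, tiny_catalog):
        spec = sb.case_spectrum(tiny_catalog, "C2", resolution=6)
        # C2's SNVs: one silent C>T and one G>T (collapses to C>A)
        assert spec.n_mutations == 2
        assert spec.values[sb.CLASS6.index("C>T")] == pytest.approx(0.5)
        assert spec.values[sb.CLASS6.index("C>A")] == pytest.approx(0.5)
        assert spec.values.sum() == pytest.approx(1.0)

    def test_zero_snv_case_is_zero_vector(self, tiny_catalog):
        spec = sb.case_spectrum(tiny_catalog, "C3", resolution=96)
        assert spec.n_mutations == 0
        assert np.all(spec.values == 0)

    def test_unknown_case_error(self, tiny_catalog):
        with pytest.raises(KeyError):
            sb.case_spectrum(tiny_catalog, "nope")

    def test_point_mass_signature_recovered(self):
        sig = np.zeros(96)
        sig[sb.CONTEXTS96.index("A[C>A]A")] = 1.0
        draws = draw_contexts(sig, 30, seed=1)
        records = [make_snv("C1", "G", "1", 10 + i, ctx[1], cls[2],
                            context3=ctx)
                   for i, (cls, ctx) in enumerate(draws)]
        cat = MutationCatalog(records=records, case_roster=["C1"])
        spec = sb.case_spectrum(cat, "C1", resolution=96)
        assert spec.values[sb.CONTEXTS96.index("A[C>A]A")] == 1.0


class TestContextFraction:
    def test_fraction_of_matching_contexts(self, tiny_catalog):
        # C1 has 3 T>C mutations, 2 at CTG
        frac = sb.context_fraction(tiny_catalog, ["C1"], "T>C", "CTG")
        assert frac == pytest.approx(2 / 3)

    def test_wildcard_pattern_is_one(self, tiny_catalog):
        assert sb.context_fraction(tiny_catalog, ["C1"], "T>C", "NTN") == 1.0

    def test_empty_class_is_zero(self, tiny_catalog):
        assert sb.context_fraction(tiny_catalog, ["C1"], "T>G", "NTN") == 0.0

    def test_incompatible_pattern_error(self, tiny_catalog):
        with pytest.raises(ValueError):
            sb.context_fraction(tiny_catalog, ["C1"], "T>C", "ACA")


class TestApobecEnrichment:
    def test_all_tcw_against_background_share(self):
        records = [make_snv("C1", "G", "1", i + 1, "C", "T", context3="TCA")
                   for i in range(10)]
        cat = MutationCatalog(records=records, case_roster=["C1"])
        # background: TCW holds 0.1 of the C-context mass
        bg = {"TCA": 0.05, "TCT": 0.05, "ACA": 0.9}
        assert sb.apobec_enrichment(cat, ["C1"], bg) == pytest.approx(10.0)

    def test_uniform_null_is_one(self):
        sig = builtin_signature("uniform")
        draws = draw_contexts(sig, 20000, seed=2)
        records = [make_snv("C1", "G", str(1 + i % 22), i + 1, ctx[1], cls[2],
                            context3=ctx)
                   for i, (cls, ctx) in enumerate(draws)]
        cat = MutationCatalog(records=records, case_roster=["C1"])
        score = sb.apobec_enrichment(cat, ["C1"],
                                     sb.uniform_context_background())
        assert score == pytest.approx(1.0, abs=0.12)

    def test_no_c_mutations_degenerate(self):
        records = [make_snv("C1", "G", "1", 1, "T", "C", context3="ATA")]
        cat = MutationCatalog(records=records, case_roster=["C1"])
        with pytest.warns(UserWarning):
            assert sb.apobec_enrichment(
                cat, ["C1"], sb.uniform_context_background()) == 0.0

    def test_missing_background_error(self, tiny_catalog):
        with pytest.raises(ValueError):
            sb.apobec_enrichment(tiny_catalog, ["C1"], {})


class TestGroupComparison:
    def test_identical_groups_null(self, tiny_catalog):
        res = sb.compare_group_spectra(tiny_catalog, ["C1", "C2"],
                                       ["C1", "C2"])
        for t, p in res.values():
            assert t == 0.0 and p == 1.0

    def test_smoking_signature_separates_c_to_a(self):
        rng = np.random.default_rng(3)
        smoking, aging = builtin_signature("smoking"), builtin_signature("aging")
        records, roster = [], []
        for g, sig in (("S", smoking), ("B", aging)):
            for i in range(50):
                case = f"{g}{i}"
                roster.append(case)
                for j, (cls, ctx) in enumerate(draw_contexts(sig, 40, rng)):
                    records.append(make_snv(case, "G", "1", j + 1, ctx[1],
                                            cls[2], context3=ctx))
        cat = MutationCatalog(records=records, case_roster=roster)
        res = sb.compare_group_spectra(
            cat, [c for c in roster if c[0] == "S"],
            [c for c in roster if c[0] == "B"])
        t, p = res["C>A"]
        assert p < 0.05 and t > 0

    def test_small_group_error(self, tiny_catalog):
        with pytest.raises(ValueError):
            sb.compare_group_spectra(tiny_catalog, ["C1"], ["C1", "C2"])


class TestClusterSpectra:
    def _blocks(self):
        a = sb.SpectrumVector(6, np.r_[1.0, 0, 0, 0, 0, 0], 10)
        b = sb.SpectrumVector(6, np.r_[0, 0, 0, 0, 1.0, 0], 10)
        return [a, a, a, b, b, b]

    def test_recovers_duplicated_blocks(self):
        labels, _ = sb.cluster_spectra(self._blocks(), 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_permutation_invariance(self):
        spectra = self._blocks()
        labels, _ = sb.cluster_spectra(spectra, 2)
        perm = [3, 0, 4, 1, 5, 2]
        labels_p, _ = sb.cluster_spectra([spectra[i] for i in perm], 2)
        # same partition after permuting back
        assert [labels_p[perm.index(i)] == labels_p[perm.index(j)]
                for i in range(6) for j in range(6)] == \
               [labels[i] == labels[j] for i in range(6) for j in range(6)]

    def test_single_case_error(self):
        with pytest.raises(ValueError):
            sb.cluster_spectra(self._blocks()[:1], 2)


class TestBurden:
    def test_zero_roster_counts(self):
        cat = MutationCatalog(records=[], case_roster=["A", "B", "C"])
        assert sb.nonsilent_burden(cat) == {"A": 0, "B": 0, "C": 0}

    def test_silent_excluded(self, tiny_catalog):
        counts = sb.nonsilent_burden(tiny_catalog)
        assert counts["C1"] == 4
        assert counts["C2"] == 2   # one silent excluded, indel counts
        assert counts["C3"] == 0


class TestMutatorEnrichment:
    def test_no_flags(self):
        burdens = {f"C{i}": i for i in range(8)}
        flags = {c: False for c in burdens}
        overlap, p = sb.mutator_enrichment(burdens, flags)
        assert overlap == 0 and p == pytest.approx(1.0)

    def test_enumerated_example(self):
        # 8 cases -> top quartile of 2; both flagged cases in it:
        # p = C(2,2)C(6,0)/C(8,2) = 1/28
        burdens = {f"C{i}": 10 - i for i in range(8)}
        flags = {c: c in ("C0", "C1") for c in burdens}
        overlap, p = sb.mutator_enrichment(burdens, flags)
        assert overlap == 2
        assert p == pytest.approx(1 / 28)

    def test_matches_exhaustive_enumeration_small_rosters(self):
        rng = np.random.default_rng(4)
        for n in (6, 9, 12):
            burdens = {f"C{i}": int(rng.integers(0, 50)) for i in range(n)}
            k = int(rng.integers(1, n))
            flagged = set(rng.choice(n, size=k, replace=False))
            flags = {f"C{i}": i in flagged for i in range(n)}
            overlap, p = sb.mutator_enrichment(burdens, flags)
            q = math.ceil(n / 4)
            cases = list(burdens)
            top = set(sorted(range(n),
                             key=lambda i: (-burdens[cases[i]], i))[:q])
            total = hits = 0
            for combo in itertools.combinations(range(n), k):
                total += 1
                if len(set(combo) & top) >= overlap:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_tied_burdens_warn(self):
        burdens = {f"C{i}": 5 for i in range(4)}
        flags = {c: False for c in burdens}
        with pytest.warns(UserWarning):
            sb.mutator_enrichment(burdens, flags)


class TestSignificantGeneFilter:
    def test_count_and_p_thresholds(self):
        per_gene = {"LOWCOUNT": (3, 1e-9), "KEPT": (4, 0.049),
                    "HIGHP": (10, 0.06), "BEST": (6, 0.001)}
        assert sb.significant_gene_filter(per_gene, 109) == ["BEST", "KEPT"]

    def test_empty_table(self):
        assert sb.significant_gene_filter({}, 109) == []
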