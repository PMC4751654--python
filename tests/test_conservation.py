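"""Alignment mapping, conserved-pair decisions, conservation classes and
clade-common classification."""

import numpy as np
import pytest
from scipy import stats

from aarepeat import synthetic_data as synth
from aarepeat.conservation import (
    AlignedInterval,
    AlignmentError,
    CodonAlignment,
    classify_clade_common,
    classify_conservation,
    is_conserved_pair,
    map_repeat_to_alignment,
    species_only_proportion_test,
)
from aarepeat.repeat_detection import RepeatAnnotation, detect_proteome


def ann(pid, res, start, end):
    return RepeatAnnotation(pid, res, start, end, end - start, end - start)


class TestCodonAlignment:
    def test_partial_codon_gap_rejected(self):
        with pytest.raises(AlignmentError, match="partial codon"):
            CodonAlignment({"a": "ATG-AA", "b": "ATGAAA"})

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            CodonAlignment({"a": "ATGAAA", "b": "ATG"})

    def test_gapped_protein(self):
        aln = CodonAlignment({"a": "ATG---AAA", "b": "ATGGCCAAA"})
        assert aln.gapped_protein("a") == "M-K"
        assert aln.gapped_protein("b") == "MAK"
        assert aln.n_residue_columns == 3

    def test_ungap_recovers_cds(self):
        aln = CodonAlignment({"a": "ATG---AAA"})
        assert aln.ungapped("a") == "ATGAAA"


class TestMapRepeatToAlignment:
    def test_identity_when_ungapped(self):
        iv = map_repeat_to_alignment(ann("p", "A", 2, 7), "MKAAAAAGT")
        assert (iv.column_start, iv.column_end) == (2, 7)

    def test_gap_before_repeat_shifts_columns(self):
        iv = map_repeat_to_alignment(ann("p", "A", 2, 7), "MK--AAAAAGT")
        assert (iv.column_start, iv.column_end) == (4, 9)

    def test_gap_inside_repeat_widens_interval(self):
        iv = map_repeat_to_alignment(ann("p", "A", 2, 7), "MKAA--AAAGT")
        assert (iv.column_start, iv.column_end) == (2, 9)

    def test_round_trip_on_random_gapped_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(8, 40))
            residues = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n)
            gapped = []
            for ch in residues:
                while rng.random() < 0.2:
                    gapped.append("-")
                gapped.append(str(ch))
            gapped = "".join(gapped)
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            iv = map_repeat_to_alignment(ann("p", "A", s, e), gapped)
            window = gapped[iv.column_start : iv.column_end]
            assert window.replace("-", "") == "".join(residues[s:e])
            assert window[0] != "-" and window[-1] != "-"


class TestIsConservedPair:
    def _iv(self, res, a, b, sp="x"):
        return AlignedInterval(sp, ann(f"{sp}_p", res, 0, b - a), a, b)

    def test_identical_columns_same_type(self):
        assert is_conserved_pair(self._iv("A", 5, 10), self._iv("A", 5, 10, "y"))

    def test_disjoint_columns(self):
        assert not is_conserved_pair(self._iv("A", 0, 5), self._iv("A", 5, 10, "y"))

    def test_single_shared_column_suffices(self):
        assert is_conserved_pair(self._iv("A", 0, 6), self._iv("A", 5, 10, "y"))

    def test_frame_shift_type_mismatch(self):
        # same underlying nucleotide repeat read as polyP vs polyA
        assert not is_conserved_pair(self._iv("P", 5, 10), self._iv("A", 5, 10, "y"))

    def test_symmetry_on_random_intervals(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            a = self._iv(
                "AP"[rng.integers(2)],
                int(rng.integers(0, 20)),
                int(rng.integers(21, 40)),
            )
            b = self._iv(
                "AP"[rng.integers(2)],
                int(rng.integers(0, 20)),
                int(rng.integers(21, 40)),
                "y",
            )
            assert is_conserved_pair(a, b) == is_conserved_pair(b, a)


class TestClassifyConservation:
    def _family(self, plans, species=("anole", "frog", "mouse"), seed=0):
        fam = synth.generate_ortholog_family(species, plans, seed=seed, scaffold_len=52)
        catalogs = {
            sp: detect_proteome([rec.protein]) for sp, rec in fam.records.items()
        }
        alignments = {fam.alignment.protein_ids[species[0]]: fam.alignment}
        return fam, catalogs, alignments

    def test_identical_sequences_all_conserved(self):
        plans = [synth.ConservationPlan("E", 6, ("anole", "frog", "mouse"))]
        fam, catalogs, alignments = self._family(plans)
        records, _ = classify_conservation("anole", catalogs, alignments)
        assert [r.conservation_class for r in records] == ["conserved_in_all"]

    def test_planted_species_only(self):
        plans = [synth.ConservationPlan("A", 6, ("anole",))]
        _, catalogs, alignments = self._family(plans)
        records, _ = classify_conservation("anole", catalogs, alignments)
        assert records[0].conservation_class == "species_only"

    def test_presence_only_in_excluded_relative_stays_species_only(self):
        plans = [synth.ConservationPlan("Q", 6, ("anole", "mouse"))]
        _, catalogs, alignments = self._family(plans)
        records, _ = classify_conservation(
            "anole", catalogs, alignments, {"anole": ["mouse"]}
        )
        assert records[0].conservation_class == "species_only"
        assert records[0].n_conserved == 1

    def test_partition_invariant(self):
        plans = [
            synth.ConservationPlan("E", 6, ("anole", "frog", "mouse")),
            synth.ConservationPlan("A", 6, ("anole",)),
            synth.ConservationPlan("Q", 7, ("anole", "mouse")),
        ]
        _, catalogs, alignments = self._family(plans, seed=3)
        records, _ = classify_conservation("anole", catalogs, alignments)
        classes = [r.conservation_class for r in records]
        assert len(records) == len(catalogs["anole"])
        assert sorted(classes) == ["conserved_in_all", "conserved_in_k", "species_only"]

    def test_missing_alignment_goes_to_skip_report(self):
        plans = [synth.ConservationPlan("E", 6, ("anole", "frog", "mouse"))]
        _, catalogs, _ = self._family(plans)
        records, skipped = classify_conservation("anole", catalogs, {})
        assert records == []
        assert skipped == ["anole_fam1"]


class TestSpeciesOnlyProportionTest:
    def test_identical_proportions_p_one(self):
        df = species_only_proportion_test({"a": (10, 100), "b": (10, 100)})
        assert df.p_value.iloc[0] == pytest.approx(1.0)

    def test_extreme_difference_tiny_p(self):
        df = species_only_proportion_test({"a": (50, 100), "b": (5, 100)})
        assert df.p_value.iloc[0] < 1e-10

    def test_matches_hypergeometric_sum(self):
        # independent route: two-sided Fisher p as the sum of hypergeometric
        # point masses no larger than the observed table's
        table = {"a": (3, 10), "b": (8, 10)}
        df = species_only_proportion_test(table)
        M, n, N = 20, 11, 10  # total, total species-only, draws from row a
        rv = stats.hypergeom(M, n, N)
        p_obs = rv.pmf(3)
        p_exact = sum(rv.pmf(k) for k in range(0, 11) if rv.pmf(k) <= p_obs + 1e-12)
        assert df.p_value.iloc[0] == pytest.approx(p_exact, rel=1e-6)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            species_only_proportion_test({"a": (0, 0), "b": (1, 10)})


class TestCladeCommon:
    def _dataset(self, plans, availability=None, seed=0):
        clades = {"sq": ("s1", "s2", "s3"), "mm": ("m1", "m2")}
        return (
            synth.generate_clade_dataset(clades, plans, availability, seed=seed),
            clades,
        )

    def _classify(self, dataset, clades):
        catalogs = {}
        for sp, genes in dataset.records.items():
            catalogs[sp] = detect_proteome([rec.protein for rec in genes.values()])
        return classify_clade_common(catalogs, dataset.alignments, clades)

    def test_repeat_in_all_members_is_clade_common(self):
        plans = [synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2", "s3", "m1", "m2"))]
        dataset, clades = self._dataset(plans)
        matrix = self._classify(dataset, clades)
        flags = {(f.clade, f.clade_common) for f in matrix.flags}
        assert flags == {("sq", True), ("mm", True)}

    def test_repeat_missing_in_one_member_is_not(self):
        plans = [synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2", "m1", "m2"))]
        dataset, clades = self._dataset(plans)
        matrix = self._classify(dataset, clades)
        by_clade = {f.clade: f.clade_common for f in matrix.flags}
        assert by_clade == {"sq": False, "mm": True}

    def test_unavailable_species_skipped_not_absent(self):
        plans = [synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2", "m1", "m2"))]
        availability = {"g1": ("s1", "s2", "m1", "m2")}  # s3 has no sequence
        dataset, clades = self._dataset(plans, availability)
        matrix = self._classify(dataset, clades)
        by_clade = {f.clade: f.clade_common for f in matrix.flags}
        assert by_clade == {"sq": True, "mm": True}

    def test_single_available_species_flag_undefined(self):
        plans = [synth.CladeRepeatPlan("g1", "P", 6, ("s1", "m1", "m2"))]
        availability = {"g1": ("s1", "m1", "m2")}
        dataset, clades = self._dataset(plans, availability)
        matrix = self._classify(dataset, clades)
        by_clade = {f.clade: f.clade_common for f in matrix.flags}
        assert by_clade == {"sq": None, "mm": True}

    def test_counts_match_catalogs(self):
        plans = [
            synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2", "s3", "m1", "m2")),
            synth.CladeRepeatPlan("g2", "E", 7, ("s1",)),
        ]
        dataset, clades = self._dataset(plans)
        matrix = self._classify(dataset, clades)
        assert matrix.counts.loc["g1"].eq(1).all()
        assert matrix.counts.loc["g2", "s1"] == 1
        assert matrix.counts.loc["g2", "m1"] == 0
        assert matrix.totals()["s1"] == 2
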