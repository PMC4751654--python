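"""PLP, summary tables, positional classes and rank-sum comparisons."""

import itertools

import numpy as np
import pytest

from aarepeat.repeat_detection import RepeatAnnotation, RepeatCatalog, DetectorParams
from aarepeat.repeat_statistics import (
    compare_length_distributions,
    compute_plp,
    length_histogram,
    positional_class,
    position_profile,
    summarize_by_type,
)
from tests.conftest import make_paired


def ann(pid, res, start, end, main=None, core=None):
    length = end - start
    return RepeatAnnotation(pid, res, start, end, main or length, core or length)


class TestComputePlp:
    def test_single_codon_perfect_repeat(self):
        paired = make_paired("p", "AAAAA", ["GCA"] * 5)
        prof = compute_plp(ann("p", "A", 0, 5), paired)
        assert prof.plp == 1.0
        assert prof.pure_codon == "GCA"

    def test_codon_switch_breaks_run(self):
        paired = make_paired("p", "AAAAA", ["GCA", "GCA", "GCC", "GCA", "GCA"])
        prof = compute_plp(ann("p", "A", 0, 5), paired)
        assert prof.longest_pure_run == 2
        assert prof.plp == pytest.approx(0.4)
        assert prof.pure_codon is None

    def test_nonmain_codon_cannot_join_run(self):
        paired = make_paired("p", "AARAA", ["GCA", "GCA", "CGT", "GCA", "GCA"])
        prof = compute_plp(ann("p", "A", 0, 5, main=4), paired)
        assert prof.longest_pure_run == 2
        assert prof.plp == pytest.approx(0.4)

    def test_all_distinct_codons_gives_one_over_length(self):
        paired = make_paired("p", "LLLL", ["CTA", "CTC", "CTG", "CTT"])
        prof = compute_plp(ann("p", "L", 0, 4), paired)
        assert prof.plp == pytest.approx(1 / 4)

    def test_interval_out_of_range(self):
        paired = make_paired("p", "AAAAA", ["GCA"] * 5)
        with pytest.raises(ValueError):
            compute_plp(ann("p", "A", 0, 9), paired)

    def test_ambiguous_codon_breaks_run(self):
        paired = make_paired("p", "AAAAA", ["GCA", "GCA", "GCN", "GCA", "GCA"])
        assert paired.ambiguous == frozenset({2})
        prof = compute_plp(ann("p", "A", 0, 5), paired)
        assert prof.longest_pure_run == 2


class TestSummarizeByType:
    def _catalog_with_profiles(self):
        catalog = RepeatCatalog(DetectorParams())
        profiles = []
        plans = [
            ("p1", ["GCA"] * 5),
            ("p2", ["GCA"] * 5),
            ("p3", ["GCA", "GCC", "GCA", "GCC", "GCA"]),
        ]
        for pid, codons in plans:
            paired = make_paired(pid, "AAAAA", codons)
            a = ann(pid, "A", 0, 5)
            catalog.annotations.append(a)
            profiles.append(compute_plp(a, paired))
        return catalog, profiles

    def test_counts_and_pure_codon_breakdown(self):
        catalog, profiles = self._catalog_with_profiles()
        [row] = summarize_by_type(catalog, profiles)
        assert (row.main_residue, row.count, row.n_plp1) == ("A", 3, 2)
        assert row.codon_breakdown == (("GCA", 2),)

    def test_totals_conserved(self):
        catalog, profiles = self._catalog_with_profiles()
        rows = summarize_by_type(catalog, profiles)
        assert sum(r.count for r in rows) == len(catalog)

    def test_codon_skew_reflected_in_breakdown(self):
        # more GAG-pure than GAA-pure polyE repeats when planted that way
        catalog = RepeatCatalog(DetectorParams())
        profiles = []
        for i, codon in enumerate(["GAG"] * 4 + ["GAA"] * 2):
            pid = f"e{i}"
            paired = make_paired(pid, "EEEEE", [codon] * 5)
            a = ann(pid, "E", 0, 5)
            catalog.annotations.append(a)
            profiles.append(compute_plp(a, paired))
        [row] = summarize_by_type(catalog, profiles)
        assert row.codon_breakdown == (("GAG", 4), ("GAA", 2))

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_type(RepeatCatalog(DetectorParams()), [])


class TestPositionalClass:
    @pytest.mark.parametrize(
        "start,end,length,expected",
        [
            (0, 5, 100, "N"),
            (95, 100, 100, "C"),
            (45, 55, 100, "M"),  # midpoint exactly 50
            (28, 38, 100, "N"),  # midpoint 33, just below the first tercile
            (60, 74, 100, "C"),  # midpoint 67, at/above the second tercile
        ],
    )
    def test_tercile_rule(self, start, end, length, expected):
        assert positional_class(ann("p", "A", start, end), length) == expected

    def test_profile_rows_sum_to_one(self):
        catalog = RepeatCatalog(DetectorParams())
        rng = np.random.default_rng(1)
        lengths = {}
        for i in range(50):
            pid = f"p{i}"
            lengths[pid] = 120
            s = int(rng.integers(0, 110))
            catalog.annotations.append(ann(pid, "Q", s, s + 8))
        df = position_profile(catalog, lengths)
        assert np.allclose(df[["prop_N", "prop_M", "prop_C"]].sum(axis=1), 1.0)


class TestLengthHistogram:
    def test_threshold_proportion(self):
        counts, edges, prop = length_histogram([5, 6, 30], threshold=30)
        assert prop == pytest.approx(2 / 3)
        assert counts.sum() == 3

    def test_empty_catalog_is_error(self):
        with pytest.raises(ValueError):
            length_histogram([])

    def test_all_below_threshold(self):
        _, _, prop = length_histogram([5, 7, 9], threshold=30)
        assert prop == 1.0


class TestRankSum:
    def test_identical_groups_p_near_one(self):
        z, p = compare_length_distributions(range(1, 21), range(1, 21))
        assert abs(z) < 1e-9
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        _, p = compare_length_distributions(range(1, 21), range(101, 121))
        assert p < 1e-6

    def test_antisymmetric_under_swap(self):
        a, b = [3, 5, 5, 9, 12], [4, 4, 8, 15]
        za, pa = compare_length_distributions(a, b)
        zb, pb = compare_length_distributions(b, a)
        assert za == pytest.approx(-zb)
        assert pa == pytest.approx(pb)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            compare_length_distributions([], [1, 2])

    def test_matches_exact_enumeration_at_small_n(self):
        """Cross-check the normal approximation against the exact
        permutation null of the rank-sum statistic."""
        a = [1.0, 4.0, 6.0, 11.0, 13.0, 14.0, 17.0, 18.0]
        b = [2.0, 3.0, 5.0, 7.0, 12.0, 15.0, 16.0, 19.0]
        _, p_approx = compare_length_distributions(a, b)
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        observed = sum(ranks[v] for v in a)
        n = len(a)
        null = [
            sum(combo)
            for combo in itertools.combinations(range(1, len(pooled) + 1), n)
        ]
        mean = np.mean(null)
        p_exact = np.mean([abs(w - mean) >= abs(observed - mean) - 1e-9 for w in null])
        assert p_approx == pytest.approx(p_exact, abs=0.05)
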