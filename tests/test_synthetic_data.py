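"""Generator contracts: determinism, planted-truth consistency, decoys."""

import numpy as np
import pytest

from aarepeat import synthetic_data as synth
from aarepeat.conservation import validate_against_cds
from aarepeat.orthology import reciprocal_best_hits
from aarepeat.repeat_detection import detect_proteome, detect_repeats
from aarepeat.repeat_statistics import compute_plp


class TestGeneratePairedRecord:
    def test_pure_plan_recovered_with_plp_one(self):
        plan = synth.RepeatPlan("A", 7, pure=True)
        rec, [truth] = synth.generate_paired_record("p1", 80, [plan], seed=1)
        [ann] = detect_repeats(rec.protein.sequence, protein_id="p1")
        assert (ann.start, ann.end) == (truth.start, truth.end)
        assert compute_plp(ann, rec).plp == 1.0

    def test_imperfect_plan_recovered(self):
        plan = synth.RepeatPlan("Q", 6, insertions=((3, 4),))
        rec, [truth] = synth.generate_paired_record("p1", 90, [plan], seed=2)
        [ann] = detect_repeats(rec.protein.sequence, protein_id="p1")
        assert (ann.start, ann.end) == (truth.start, truth.end)
        assert ann.purity == pytest.approx(truth.purity)
        assert ann.purity == pytest.approx(10 / 13)

    def test_seed_determinism(self):
        plan = synth.RepeatPlan("E", 6)
        a, _ = synth.generate_paired_record("p1", 100, [plan], seed=9)
        b, _ = synth.generate_paired_record("p1", 100, [plan], seed=9)
        assert a.protein.sequence == b.protein.sequence
        assert a.cds.nucleotide_sequence == b.cds.nucleotide_sequence

    def test_infeasible_plan_is_error(self):
        plan = synth.RepeatPlan("A", 50)
        with pytest.raises(ValueError, match="at least"):
            synth.generate_paired_record("p1", 40, [plan], seed=0)

    def test_codon_weights_respected(self):
        plan = synth.RepeatPlan("E", 10, codon_weights={"GAG": 1.0})
        rec, [truth] = synth.generate_paired_record("p1", 80, [plan], seed=3)
        assert truth.pure_codon == "GAG"
        assert set(rec.codons[truth.start : truth.end]) == {"GAG"}

    def test_background_is_repeat_free(self):
        rec, _ = synth.generate_paired_record("p1", 400, [], seed=4)
        assert detect_repeats(rec.protein.sequence) == []

    def test_proteome_truth_exact(self):
        proteome = synth.generate_proteome(n_proteins=25, seed=12)
        catalog = detect_proteome(proteome.proteins)
        detected = {
            (a.protein_id, a.main_residue, a.start, a.end) for a in catalog
        }
        planted = {
            (t.protein_id, t.residue, t.start, t.end) for t in proteome.truth
        }
        assert detected == planted


class TestGenerateOrthologFamily:
    SPECIES = ("anole", "frog", "mouse")

    def test_alignment_invariants_and_cds_round_trip(self):
        fam = synth.generate_ortholog_family(
            self.SPECIES,
            [synth.ConservationPlan("E", 6, self.SPECIES)],
            gap_plan=[("frog", 2, 2)],
            seed=5,
        )
        cds = {
            rec.cds.protein_id: rec.cds.nucleotide_sequence
            for rec in fam.records.values()
        }
        validate_against_cds(fam.alignment, cds)

    def test_rbh_truth_recovered_against_decoys(self):
        fam = synth.generate_ortholog_family(
            self.SPECIES, [synth.ConservationPlan("E", 6, self.SPECIES)], seed=6
        )
        for sp in self.SPECIES[1:]:
            pairs = reciprocal_best_hits(
                fam.hit_tables[("anole", sp)], fam.hit_tables[(sp, "anole")]
            )
            assert pairs == {
                (fam.alignment.protein_ids["anole"], fam.alignment.protein_ids[sp])
            }

    def test_frame_shift_decoy_translates_differently(self):
        fam = synth.generate_ortholog_family(
            self.SPECIES,
            [synth.ConservationPlan("P", 6, ("anole",), decoy_residue="A")],
            seed=7,
        )
        anole = fam.records["anole"].protein.sequence
        frog = fam.records["frog"].protein.sequence
        assert "P" * 6 in anole and "A" * 6 not in anole
        assert "A" * 6 in frog and "P" * 6 not in frog
        # the decoy codons spell the same repeated nucleotide pattern
        assert "CCGCCG" in fam.records["anole"].cds.nucleotide_sequence
        assert "GCCGCC" in fam.records["frog"].cds.nucleotide_sequence

    def test_planted_repeats_detected_in_every_species(self):
        fam = synth.generate_ortholog_family(
            self.SPECIES,
            [
                synth.ConservationPlan("E", 6, self.SPECIES),
                synth.ConservationPlan("A", 7, ("anole", "mouse")),
            ],
            seed=8,
            scaffold_len=60,
        )
        for sp, rec in fam.records.items():
            detected = {
                (a.main_residue, a.start, a.end)
                for a in detect_repeats(rec.protein.sequence)
            }
            planted = {
                (t.residue, t.start, t.end) for t in fam.truth.planted[sp]
            }
            assert detected == planted

    def test_seed_determinism(self):
        kwargs = dict(
            species=self.SPECIES,
            plans=[synth.ConservationPlan("E", 6, self.SPECIES)],
        )
        a = synth.generate_ortholog_family(seed=11, **kwargs)
        b = synth.generate_ortholog_family(seed=11, **kwargs)
        assert a.alignment.sequences == b.alignment.sequences


class TestGenerateGoTable:
    def test_planted_labels_recovered(self):
        from aarepeat.functional_profiles import assign_functional_group

        plan = {
            "p1": "TF_Development",
            "p2": "Signal",
            "p3": "Metabolism",
            "p4": "Others",
        }
        table, truth = synth.generate_go_table(plan, seed=13)
        for pid, group in truth.items():
            assert assign_functional_group(table[pid]) == group

    def test_adversarial_terms_are_lower_priority_only(self):
        from aarepeat.functional_profiles import DEFAULT_KEYWORDS

        plan = {f"p{i}": "Signal" for i in range(50)}
        table, _ = synth.generate_go_table(plan, seed=14, adversarial=True)
        tf_phrases = DEFAULT_KEYWORDS[0][1]
        for terms in table.values():
            assert not any(
                phrase in term.lower() for term in terms for phrase in tf_phrases
            )

    def test_determinism(self):
        plan = {f"p{i}": "Metabolism" for i in range(20)}
        a, _ = synth.generate_go_table(plan, seed=15)
        b, _ = synth.generate_go_table(plan, seed=15)
        assert a == b


class TestGenerateCladeDataset:
    def test_expected_flags_consistent_with_plan(self):
        clades = {"sq": ("s1", "s2"), "mm": ("m1", "m2", "m3")}
        plans = [
            synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2", "m1", "m2", "m3")),
            synth.CladeRepeatPlan("g2", "A", 6, ("s1",)),
        ]
        ds = synth.generate_clade_dataset(clades, plans, seed=16)
        assert ds.expected_clade_common(plans[0], "sq") is True
        assert ds.expected_clade_common(plans[0], "mm") is True
        assert ds.expected_clade_common(plans[1], "sq") is False

    def test_unavailable_species_absent_from_alignment(self):
        clades = {"sq": ("s1", "s2", "s3")}
        plans = [synth.CladeRepeatPlan("g1", "P", 6, ("s1", "s2"))]
        ds = synth.generate_clade_dataset(
            clades, plans, {"g1": ("s1", "s2")}, seed=17
        )
        assert set(ds.alignments["g1"].species) == {"s1", "s2"}
        assert ds.expected_clade_common(plans[0], "sq") is True


class TestPlantedRecoveryRates:
    def _random_plan(self, rng):
        plantable = [aa for aa in synth.AMINO_ACIDS if aa not in ("M", "W")]
        residue = plantable[rng.integers(len(plantable))]
        core = int(rng.integers(5, 12))
        insertions = ()
        if rng.random() < 0.5:
            insertions = ((int(rng.integers(1, 5)), int(rng.integers(2, 7))),)
        plan = synth.RepeatPlan(residue, core, insertions)
        if plan.purity < 0.75:
            plan = synth.RepeatPlan(residue, core)
        return plan

    def test_exact_recovery_of_clean_plants(self):
        """Planted tracts with purity >= 0.75 and non-main runs <= 4 are
        recovered at exact coordinates in >= 99 % of 1000 seeded trials."""
        rng = np.random.default_rng(314)
        hits = 0
        n_trials = 1000
        for i in range(n_trials):
            plan = self._random_plan(rng)
            rec, [truth] = synth.generate_paired_record(
                f"p{i}", plan.length + 40, [plan], rng
            )
            anns = detect_repeats(rec.protein.sequence, protein_id=f"p{i}")
            if [(a.main_residue, a.start, a.end) for a in anns] == [
                (truth.residue, truth.start, truth.end)
            ]:
                hits += 1
        assert hits >= 0.99 * n_trials

    def test_coverage_under_point_mutation_noise(self):
        """With point mutations at rate 0.02 inside tracts, detected
        intervals still cover >= 95 % of planted residues overall."""
        rng = np.random.default_rng(315)
        covered = total = 0
        for i in range(1000):
            plan = self._random_plan(rng)
            rec, [truth] = synth.generate_paired_record(
                f"p{i}", plan.length + 40, [plan], rng, mutation_rate=0.02
            )
            got = set()
            for a in detect_repeats(rec.protein.sequence):
                if a.main_residue == truth.residue:
                    got.update(range(a.start, a.end))
            planted = set(range(truth.start, truth.end))
            covered += len(planted & got)
            total += len(planted)
        assert covered / total >= 0.95
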