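import numpy as np
import pytest

from conftest import make_table, random_table
from mirsig.consensus import (direction_stratify, partition_signatures,
                              strict_intersection, vote_consensus)
from mirsig.deg_classification import ThresholdConfig
from mirsig.synthetic_data import (CohortDesign, DiseaseDesign, SyntheticSpec,
                                   generate_cohort_pair)

T = ThresholdConfig()


def pair(rows1, rows2, disease="D"):
    return (make_table(rows1, "c1", disease), make_table(rows2, "c2", disease))


class TestStrictIntersection:
    def test_concordant_significant_gene_included(self):
        t1, t2 = pair([("G", 2.0, 1e-5)], [("G", 2.0, 1e-5)])
        sig = strict_intersection(t1, t2, T)
        assert sig.symbols == {"G"}
        assert sig.direction_of("G") == "up"
        assert sig.members["G"].support == "both_significant"

    def test_discordant_gene_excluded(self):
        t1, t2 = pair([("G", 2.0, 1e-5)], [("G", -2.0, 1e-5)])
        assert len(strict_intersection(t1, t2, T)) == 0

    def test_one_cohort_not_significant_excluded(self):
        t1, t2 = pair([("G", 2.0, 1e-5)], [("G", 2.0, 0.2)])
        assert len(strict_intersection(t1, t2, T)) == 0

    def test_disjoint_universes_give_empty_signature(self):
        t1, t2 = pair([("A", 2.0, 1e-5)], [("B", 2.0, 1e-5)])
        assert len(strict_intersection(t1, t2, T)) == 0


class TestVoteConsensus:
    def test_one_significant_cohort_suffices(self):
        t1, t2 = pair([("G", 1.5, 0.01)], [("G", 1.2, 0.2)])
        sig = vote_consensus(t1, t2, T)
        assert sig.symbols == {"G"}
        assert sig.members["G"].support == "one_significant"

    def test_significant_in_neither_excluded(self):
        t1, t2 = pair([("G", 1.5, 0.2)], [("G", 1.2, 0.2)])
        assert len(vote_consensus(t1, t2, T)) == 0

    def test_fold_change_must_hold_in_both(self):
        t1, t2 = pair([("G", 1.5, 0.01)], [("G", 0.8, 0.01)])
        assert len(vote_consensus(t1, t2, T)) == 0

    def test_zero_log2fc_never_concordant(self):
        t1, t2 = pair([("G", 0.0, 0.001)], [("G", 0.0, 0.001)])
        assert len(vote_consensus(
            t1, t2, ThresholdConfig(abs_lfc_min=0.0))) == 0


class TestConsensusProperties:
    def test_strict_subset_of_vote_on_random_pairs(self, rng):
        for _ in range(50):
            t1 = random_table(rng, 80, "c1")
            t2 = random_table(rng, 80, "c2")
            strict = strict_intersection(t1, t2, T).symbols
            vote = vote_consensus(t1, t2, T).symbols
            assert strict <= vote

    def test_symmetry_in_cohort_order(self, rng):
        t1 = random_table(rng, 60, "c1")
        t2 = random_table(rng, 60, "c2")
        for rule in (strict_intersection, vote_consensus):
            ab = rule(t1, t2, T)
            ba = rule(t2, t1, T)
            assert ab.symbols == ba.symbols
            assert all(ab.direction_of(s) == ba.direction_of(s)
                       for s in ab.symbols)

    def test_planted_program_recovered_exactly_at_high_snr(self):
        # program, one-cohort distractors and discordant genes all with
        # effects far above the noise floor: strict consensus must equal
        # the planted concordant program exactly
        spec = SyntheticSpec(
            n_genes=400,
            diseases=(DiseaseDesign(
                name="D", cohorts=(CohortDesign(30, 30), CohortDesign(30, 30)),
                n_program_up=25, n_program_down=25,
                n_distractor=20, n_discordant=10,
            ),),
            effect_mean=4.0, effect_sd=0.2, effect_floor=3.0,
            null_sd=0.0, sample_sd=0.3, seed=7,
        )
        t1, t2, truth = generate_cohort_pair(spec, "D")
        sig = strict_intersection(t1, t2, T)
        assert dict((s, g.direction) for s, g in sig.members.items()) == \
            truth.concordant_program("D")


class TestPartition:
    def test_enumerated_example(self):
        a = strict_intersection(
            *pair([("P", 2, 1e-5), ("Q", 2, 1e-5), ("R", -2, 1e-5)],
                  [("P", 2, 1e-5), ("Q", 2, 1e-5), ("R", -2, 1e-5)], "A"))
        b = strict_intersection(
            *pair([("Q", -2, 1e-5), ("S", -2, 1e-5)],
                  [("Q", -2, 1e-5), ("S", -2, 1e-5)], "B"))
        p = partition_signatures(a, b)
        assert set(p.a_specific) == {"P", "R"}
        assert set(p.b_specific) == {"S"}
        assert p.shared_discordant == {"Q": ("up", "down")}
        assert p.shared_concordant == {}

    def test_disjoint_signatures(self):
        a = strict_intersection(*pair([("A", 2, 1e-5)], [("A", 2, 1e-5)], "A"))
        b = strict_intersection(*pair([("B", 2, 1e-5)], [("B", 2, 1e-5)], "B"))
        p = partition_signatures(a, b)
        assert set(p.a_specific) == {"A"} and set(p.b_specific) == {"B"}
        assert not p.shared_symbols

    def test_identical_signatures_all_shared_concordant(self):
        rows = [("X", 2, 1e-5), ("Y", -2, 1e-5)]
        a = strict_intersection(*pair(rows, rows, "A"))
        b = strict_intersection(*pair(rows, rows, "B"))
        p = partition_signatures(a, b)
        assert not p.a_specific and not p.b_specific
        assert p.shared_concordant == {"X": "up", "Y": "down"}

    def test_partition_identities_on_random_signatures(self, rng):
        for _ in range(50):
            t1 = random_table(rng, 60, "c1", "A")
            t2 = random_table(rng, 60, "c2", "A")
            t3 = random_table(rng, 60, "c3", "B")
            t4 = random_table(rng, 60, "c4", "B")
            a = vote_consensus(t1, t2, T)
            b = vote_consensus(t3, t4, T)
            p = partition_signatures(a, b)
            shared = p.shared_symbols
            assert len(p.a_specific) + len(shared) == len(a)
            assert len(p.b_specific) + len(shared) == len(b)
            parts = [set(p.a_specific), set(p.b_specific),
                     set(p.shared_concordant), set(p.shared_discordant)]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not (parts[i] & parts[j])
            assert set().union(*parts) == a.symbols | b.symbols


class TestDirectionStratify:
    def _partition(self):
        a = strict_intersection(
            *pair([("P", 2, 1e-5), ("Q", 2, 1e-5), ("R", -2, 1e-5)],
                  [("P", 2, 1e-5), ("Q", 2, 1e-5), ("R", -2, 1e-5)], "A"))
        b = strict_intersection(
            *pair([("Q", -2, 1e-5), ("S", -2, 1e-5)],
                  [("Q", -2, 1e-5), ("S", -2, 1e-5)], "B"))
        return partition_signatures(a, b)

    def test_six_sets_emitted(self):
        sets = direction_stratify(self._partition(), min_set_size=1)
        assert set(sets) == {
            "A_specific_up", "A_specific_down", "B_specific_up",
            "B_specific_down", "shared_concordant", "shared_discordant",
        }
        assert sets["A_specific_up"].symbols == {"P"}
        assert sets["A_specific_down"].symbols == {"R"}
        assert sets["B_specific_down"].symbols == {"S"}
        assert sets["shared_discordant"].symbols == {"Q"}

    def test_small_sets_flagged_underpowered_but_emitted(self):
        sets = direction_stratify(self._partition(), min_set_size=5)
        assert sets["A_specific_up"].underpowered
        assert len(sets["A_specific_up"]) == 1

    def test_empty_partition_gives_six_empty_sets(self):
        a = strict_intersection(*pair([("A", 0.1, 0.9)], [("A", 0.1, 0.9)], "A"))
        b = strict_intersection(*pair([("B", 0.1, 0.9)], [("B", 0.1, 0.9)], "B"))
        sets = direction_stratify(partition_signatures(a, b))
        assert len(sets) == 6
        assert all(len(s) == 0 for s in sets.values())
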