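import numpy as np
import pandas as pd
import pytest

from mirsig.consensus import strict_intersection, partition_signatures
from mirsig.deg_classification import ThresholdConfig
from mirsig.errors import ConfigError
from mirsig.ora import enrich_signature
from mirsig.synthetic_data import (CohortDesign, DiseaseDesign, HubDesign,
                                   LibraryDesign, SyntheticSpec,
                                   consensus_recovery, default_spec,
                                   generate_cohort_pair, generate_study,
                                   generate_target_library,
                                   partition_recovery, truth_recovery_report)
from mirsig.target_library import universe_from_symbols

T = ThresholdConfig()


def zero_noise_spec(seed=0, **overrides):
    params = dict(
        n_genes=300,
        diseases=(DiseaseDesign(
            name="D", cohorts=(CohortDesign(5, 5, 0.0), CohortDesign(5, 5, 0.0)),
            n_program_up=20, n_program_down=20,
            n_distractor=10, n_discordant=6,
        ),),
        library=LibraryDesign(
            n_mirnas=20, regulon_size_range=(10, 30),
            hubs=(HubDesign("hub", 30, ("D", "up"), rho=4.0),),
        ),
        effect_mean=3.0, effect_sd=0.0, effect_floor=1.0,
        null_sd=0.0, sample_sd=1.0, seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


class TestSpecValidation:
    def test_planted_counts_must_fit_universe(self):
        with pytest.raises(ConfigError, match="exceed"):
            zero_noise_spec(n_genes=50)

    def test_shared_genes_require_two_diseases(self):
        with pytest.raises(ConfigError, match="two diseases"):
            zero_noise_spec(n_shared_concordant=2)

    def test_tiny_arms_rejected(self):
        with pytest.raises(ConfigError, match=">= 2 samples"):
            CohortDesign(1, 5)

    def test_oversized_regulon_rejected(self):
        with pytest.raises(ConfigError):
            zero_noise_spec(
                library=LibraryDesign(n_mirnas=5, regulon_size_range=(10, 500))
            )


class TestGenerateCohortPair:
    def test_zero_noise_all_planted_significant_in_both(self):
        t1, t2, truth = generate_cohort_pair(zero_noise_spec(), "D")
        sig = strict_intersection(t1, t2, T)
        expected = truth.concordant_program("D")
        called = {s: g.direction for s, g in sig.members.items()}
        assert called == expected

    def test_same_seed_identical_tables(self):
        a1, a2, _ = generate_cohort_pair(zero_noise_spec(seed=3), "D")
        b1, b2, _ = generate_cohort_pair(zero_noise_spec(seed=3), "D")
        pd.testing.assert_frame_equal(a1.df, b1.df)
        pd.testing.assert_frame_equal(a2.df, b2.df)

    def test_different_seed_differs(self):
        a1, _, _ = generate_cohort_pair(zero_noise_spec(seed=3), "D")
        b1, _, _ = generate_cohort_pair(zero_noise_spec(seed=4), "D")
        assert not a1.df["log2fc"].equals(b1.df["log2fc"])

    def test_discordant_genes_flip_sign_between_cohorts(self):
        t1, t2, truth = generate_cohort_pair(zero_noise_spec(), "D")
        disc = truth.df.loc[truth.df["role"] == "discordant", "symbol"]
        assert len(disc) == 6
        lfc1 = t1.df.set_index("symbol").loc[disc, "log2fc"]
        lfc2 = t2.df.set_index("symbol").loc[disc, "log2fc"]
        assert (np.sign(lfc1) == -np.sign(lfc2)).all()

    def test_shared_discordant_opposite_between_diseases(self):
        spec = default_spec(seed=5)
        study = generate_study(spec)
        _, disc = study.truth.shared_sets()
        assert len(disc) == 3
        for dir_a, dir_b in disc.values():
            assert {dir_a, dir_b} == {"up", "down"}

    def test_fdr_internally_consistent_with_pvalues(self):
        noisy = zero_noise_spec(
            diseases=(DiseaseDesign(
                name="D",
                cohorts=(CohortDesign(5, 5, 1.0), CohortDesign(5, 5, 1.0)),
                n_program_up=20, n_program_down=20,
                n_distractor=10, n_discordant=6,
            ),),
        )
        t1, _, _ = generate_cohort_pair(noisy, "D")
        from oracles import bh_stepup_reference

        assert np.allclose(
            t1.df["fdr"], np.clip(bh_stepup_reference(t1.df["pvalue"]),
                                  1e-300, 1.0)
        )


class TestGenerateTargetLibrary:
    def test_same_seed_identical_library(self):
        spec = zero_noise_spec(seed=9)
        truth = generate_study(spec).truth
        lib_a, man_a = generate_target_library(spec, truth)
        lib_b, man_b = generate_target_library(spec, truth)
        assert lib_a.regulons == lib_b.regulons
        pd.testing.assert_frame_equal(man_a, man_b)

    def test_hub_regulon_contains_manifest_overlap(self):
        spec = zero_noise_spec()
        truth = generate_study(spec).truth
        lib, manifest = generate_target_library(spec, truth)
        row = manifest.iloc[0]
        program = truth.program_symbols("D", "up")
        realized = len(lib.regulons["hub"] & program)
        assert realized == row["n_program_targets"]
        assert row["rho_realized"] == pytest.approx(
            (realized / row["regulon_size"]) / (len(program) / spec.n_genes)
        )

    def test_zero_noise_hub_degree_equals_manifest_overlap(self):
        spec = zero_noise_spec()
        study = generate_study(spec)
        lib, manifest = generate_target_library(spec, study.truth)
        t1, t2 = study.tables["D"]
        sig = strict_intersection(t1, t2, T)
        up = {s for s, g in sig.members.items() if g.direction == "up"}
        from mirsig.network import build_bipartite

        net = build_bipartite(["hub"], {s: "up" for s in up}, lib)
        assert net.degree("hub") == manifest.iloc[0]["n_program_targets"]


class TestRecoveryReport:
    def test_perfect_zero_noise_run(self):
        spec = zero_noise_spec()
        study = generate_study(spec)
        sig = strict_intersection(*study.tables["D"], T)
        rec = consensus_recovery(sig, study.truth, "D")
        assert rec["precision"] == 1.0 and rec["recall"] == 1.0

    def test_empty_consensus_has_zero_recall(self):
        spec = zero_noise_spec()
        study = generate_study(spec)
        t1, t2 = study.tables["D"]
        empty = strict_intersection(
            t1, t2, ThresholdConfig(fdr_max=1e-200, abs_lfc_min=50.0))
        rec = consensus_recovery(empty, study.truth, "D")
        assert rec["recall"] == 0.0

    def test_partition_recovery_on_default_preset(self):
        # zero-noise variant of the two-disease preset: planted shared sets
        # must be recovered exactly
        base = default_spec(seed=2)
        spec = SyntheticSpec(
            n_genes=base.n_genes,
            diseases=tuple(
                DiseaseDesign(
                    name=d.name,
                    cohorts=(CohortDesign(5, 5, 0.0), CohortDesign(5, 5, 0.0)),
                    n_program_up=d.n_program_up,
                    n_program_down=d.n_program_down,
                    n_distractor=d.n_distractor,
                    n_discordant=d.n_discordant,
                )
                for d in base.diseases
            ),
            library=base.library,
            n_shared_concordant=2, n_shared_discordant=3,
            effect_mean=3.0, effect_sd=0.0, null_sd=0.0, seed=2,
        )
        study = generate_study(spec)
        a = strict_intersection(*study.tables["CLL"], T)
        b = strict_intersection(*study.tables["MM"], T)
        rec = partition_recovery(partition_signatures(a, b), study.truth)
        assert all(v == 1.0 for v in rec.values())

    def test_report_assembles_all_stages(self):
        spec = zero_noise_spec()
        study = generate_study(spec)
        sig = strict_intersection(*study.tables["D"], T)
        report = truth_recovery_report(
            {"D": sig}, None, study.truth, hub_ranks={"hub": 1}
        )
        assert report["consensus_D"]["recall"] == 1.0
        assert report["hub_ranks"]["hub"] == 1


def test_planted_hub_wins_enrichment_at_zero_noise():
    spec = zero_noise_spec()
    study = generate_study(spec)
    lib, manifest = generate_target_library(spec, study.truth)
    sig = strict_intersection(*study.tables["D"], T)
    up = {s for s, g in sig.members.items() if g.direction == "up"}
    universe = universe_from_symbols(study.truth.universe)
    res = enrich_signature(up, lib, universe)
    assert res.iloc[0]["mirna"] == "hub"
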