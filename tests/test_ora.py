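import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirsig.errors import MirsigError
from mirsig.ora import (bh_adjust, enrich_signature, enrichment_ratio,
                        hypergeom_pvalue, top_barplot_table)
from mirsig.target_library import TargetLibrary, universe_from_symbols
from oracles import bh_stepup_reference, hypergeom_tail_by_enumeration, \
    overlap_tail_table


class TestHypergeomPvalue:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_pvalue(0, 5, 4, 10) == 1.0

    def test_exhaustive_enumeration_examples(self):
        # N=10, K=5, n=4: full overlap and partial overlap, counted by
        # enumerating all 210 4-subsets
        assert hypergeom_pvalue(4, 5, 4, 10) == pytest.approx(5 / 210)
        assert hypergeom_pvalue(2, 5, 4, 10) == pytest.approx(155 / 210)

    def test_matches_enumeration_on_a_grid(self):
        for N in (5, 8, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    tails = overlap_tail_table(K, n, N)
                    for k in range(min(K, n) + 1):
                        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            tails[k], abs=1e-12
                        )

    def test_equivalent_to_one_sided_fisher(self):
        # same 2x2 table, 'greater' alternative
        k, K, n, N = 6, 20, 15, 100
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        _, fisher_p = stats.fisher_exact(table, alternative="greater")
        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(fisher_p)

    def test_tail_monotone_in_k(self):
        ps = [hypergeom_pvalue(k, 10, 8, 40) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("k,K,n,N", [(5, 4, 10, 20), (1, 25, 4, 20),
                                         (-1, 5, 5, 20), (3, 5, 2, 20)])
    def test_bound_violations_raise(self, k, K, n, N):
        with pytest.raises(MirsigError):
            hypergeom_pvalue(k, K, n, N)


class TestEnrichmentRatio:
    def test_null_expectation_is_one(self):
        assert enrichment_ratio(2, 5, 4, 10) == pytest.approx(1.0)

    def test_closed_form(self):
        assert enrichment_ratio(4, 5, 4, 10) == pytest.approx(2.0)

    def test_zero_overlap(self):
        assert enrichment_ratio(0, 5, 4, 10) == 0.0

    def test_undefined_for_empty_margins(self):
        with pytest.raises(MirsigError):
            enrichment_ratio(0, 0, 4, 10)
        with pytest.raises(MirsigError):
            enrichment_ratio(0, 5, 0, 10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx(
            [0.03, 0.03, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_cap_at_one(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(MirsigError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=60))
    def test_matches_reference_and_dominates_raw(self, pvals):
        adjusted = bh_adjust(pvals)
        assert np.allclose(adjusted, bh_stepup_reference(pvals), atol=1e-12)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestEnrichSignature:
    def universe(self):
        return universe_from_symbols([f"G{i}" for i in range(1, 11)])

    def test_known_contingency(self):
        lib = TargetLibrary({"m1": frozenset(f"G{i}" for i in range(1, 6))})
        res = enrich_signature([f"G{i}" for i in range(1, 5)], lib,
                               self.universe())
        row = res.iloc[0]
        assert (row["k"], row["n"], row["K"], row["N"]) == (4, 4, 5, 10)
        assert row["pvalue"] == pytest.approx(5 / 210)
        assert row["ratio"] == pytest.approx(2.0)
        assert row["overlap"] == "G1;G2;G3;G4"

    def test_disjoint_regulon(self):
        lib = TargetLibrary({"m1": frozenset({"G9", "G10"})})
        res = enrich_signature(["G1", "G2"], lib, self.universe())
        row = res.iloc[0]
        assert row["k"] == 0 and row["pvalue"] == 1.0 and row["ratio"] == 0.0

    def test_bh_family_is_all_regulons_of_the_signature(self):
        lib = TargetLibrary({
            "hit": frozenset(f"G{i}" for i in range(1, 6)),
            "miss": frozenset({"G9", "G10"}),
        })
        res = enrich_signature([f"G{i}" for i in range(1, 5)], lib,
                               self.universe())
        hit = res.set_index("mirna").loc["hit"]
        # m=2 tests, the smaller p doubles (i=1) before capping
        assert hit["fdr"] == pytest.approx(2 * 5 / 210)

    def test_empty_signature_warns_and_returns_empty(self):
        lib = TargetLibrary({"m": frozenset({"G1"})})
        with pytest.warns(UserWarning, match="underpowered"):
            res = enrich_signature([], lib, self.universe())
        assert res.empty

    def test_genes_outside_universe_dropped_with_warning(self):
        lib = TargetLibrary({"m": frozenset({"G1"})})
        with pytest.warns(UserWarning, match="outside the universe"):
            res = enrich_signature(["G1", "ZZZ"], lib, self.universe())
        assert res.iloc[0]["n"] == 1

    def test_small_set_flagged_not_dropped(self):
        lib = TargetLibrary({"tiny": frozenset({"G1"})})
        res = enrich_signature(["G1", "G2"], lib, self.universe(), K_min=5)
        assert len(res) == 1 and bool(res.iloc[0]["small_set"])

    def test_barplot_table(self):
        lib = TargetLibrary({"m1": frozenset(f"G{i}" for i in range(1, 6))})
        res = enrich_signature([f"G{i}" for i in range(1, 5)], lib,
                               self.universe())
        bar = top_barplot_table(res, top_m=5)
        assert bar.iloc[0]["neg_log10_fdr"] == pytest.approx(
            -np.log10(res.iloc[0]["fdr"]))
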