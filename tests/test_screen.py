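"""Screen logic: standardisation, intersection, temporal filter, QC ledger."""

import numpy as np
import pandas as pd
import pytest

from psboundary import (AmbiguousAliasError, ScreenFixtureConfig,
                        generate_screen_fixture, intersect_criteria, run_screen,
                        standardize_ids, temporal_filter)
from psboundary.screen import apply_manual_flags


class TestStandardize:
    def test_aliases_collapse_to_one_id(self):
        alias = pd.DataFrame({"symbol": ["18w", "Toll-2"],
                              "canonical_id": ["FBgn0004364", "FBgn0004364"]})
        ids, unresolved = standardize_ids(["18w", "Toll-2"], alias)
        assert ids == {"FBgn0004364"}
        assert unresolved == []

    def test_empty_alias_table_is_identity(self):
        ids, unresolved = standardize_ids(["a", "b", "b"], pd.DataFrame())
        assert ids == {"a", "b"}

    def test_unmapped_symbols_reported_not_dropped(self):
        alias = pd.DataFrame({"symbol": ["x"], "canonical_id": ["X"]})
        ids, unresolved = standardize_ids(["x", "mystery"], alias)
        assert ids == {"X", "mystery"}
        assert unresolved == ["mystery"]
        strict_ids, strict_un = standardize_ids(["x", "mystery"], alias, strict=True)
        assert strict_ids == {"X"}
        assert strict_un == ["mystery"]

    def test_ambiguous_alias_rejected(self):
        alias = pd.DataFrame({"symbol": ["dup", "dup"],
                              "canonical_id": ["A", "B"]})
        with pytest.raises(AmbiguousAliasError):
            standardize_ids(["dup"], alias)


class TestIntersection:
    def test_worked_example(self):
        got = intersect_criteria({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, {"g3", "g5"})
        assert got == {"g3"}

    def test_empty_input_gives_empty(self):
        assert intersect_criteria(set(), {"a"}, {"a"}) == set()

    def test_adding_a_gene_never_shrinks(self):
        rng = np.random.default_rng(11)
        pool = [f"g{i}" for i in range(30)]
        for _ in range(50):
            sets = [set(rng.choice(pool, rng.integers(1, 20), replace=False))
                    for _ in range(3)]
            base = intersect_criteria(*sets)
            k = rng.integers(0, 3)
            grown = [s | {"extra"} if i == k else s for i, s in enumerate(sets)]
            assert base <= intersect_criteria(*grown)


class TestTemporalFilter:
    @pytest.mark.parametrize("early_frac,keep", [(0.04, False), (0.05, True),
                                                 (0.50, True), (0.0499999, False)])
    def test_strict_five_percent_rule(self, early_frac, keep):
        got, _ = temporal_filter(early_frac * 100.0, 100.0)
        assert got is keep

    def test_zero_total_expression_distinct_reason(self):
        keep, reason = temporal_filter(0.0, 0.0)
        assert not keep and reason == "no_embryonic_expression"


class TestFlags:
    def _tables(self, genes, flagged=(), low_early=()):
        flags = pd.DataFrame({
            "canonical_id": genes,
            "not_striped_by_eye": [g in flagged for g in genes],
            "non_surface_role": [False] * len(genes),
        })
        temporal = pd.DataFrame({
            "canonical_id": genes,
            "expr_0_6h": [1.0 if g in low_early else 30.0 for g in genes],
            "expr_0_24h": [100.0] * len(genes),
        })
        return flags, temporal

    def test_no_flags_keeps_everything(self):
        genes = ["a", "b", "c"]
        flags, temporal = self._tables(genes)
        keep, ledger = apply_manual_flags(set(genes), flags, temporal)
        assert keep == set(genes) and ledger == {}

    def test_every_gene_flagged_empties_list(self):
        genes = ["a", "b"]
        flags, temporal = self._tables(genes, flagged=genes)
        keep, ledger = apply_manual_flags(set(genes), flags, temporal)
        assert keep == set()
        assert set(ledger) == set(genes)

    def test_temporal_rule_recorded_as_low_early(self):
        flags, temporal = self._tables(["a", "b"], low_early=["b"])
        keep, ledger = apply_manual_flags({"a", "b"}, flags, temporal)
        assert keep == {"a"}
        assert ledger["b"] == ["low_early_expression"]


class TestFixtureRoundTrip:
    def _brute_force(self, fx, threshold=0.05):
        amap = dict(zip(fx.alias_table.symbol, fx.alias_table.canonical_id))
        sets = []
        for syms in (fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols):
            sets.append({amap.get(s, s) for s in syms})
        inter = sets[0] & sets[1] & sets[2]
        flags = fx.flags_table.set_index("canonical_id")
        temporal = fx.temporal_table.set_index("canonical_id")
        keep = set()
        for g in inter:
            bad = bool(flags.loc[g, "not_striped_by_eye"]) \
                or bool(flags.loc[g, "non_surface_role"]) \
                or temporal.loc[g, "expr_0_6h"] / temporal.loc[g, "expr_0_24h"] < threshold
            if not bad:
                keep.add(g)
        return inter, keep

    def test_screen_recovers_planted_truth(self):
        fx = generate_screen_fixture(ScreenFixtureConfig(seed=12))
        res = run_screen(fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols,
                         fx.alias_table, fx.temporal_table, fx.flags_table)
        assert res.intersection == fx.truth["intersection"]
        assert res.post_qc == fx.truth["post_qc"]
        assert res.exclusions == fx.truth["exclusions"]

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            cfg = ScreenFixtureConfig(
                only_striped=int(rng.integers(0, 15)),
                only_surface=int(rng.integers(0, 15)),
                only_pairrule=int(rng.integers(0, 15)),
                striped_surface=int(rng.integers(0, 8)),
                striped_pairrule=int(rng.integers(0, 8)),
                surface_pairrule=int(rng.integers(0, 8)),
                all_three=int(rng.integers(0, 10)),
                n_aliases=int(rng.integers(0, 5)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fx = generate_screen_fixture(cfg)
            res = run_screen(fx.striped_symbols, fx.surface_symbols,
                             fx.pairrule_symbols, fx.alias_table,
                             fx.temporal_table, fx.flags_table)
            inter, keep = self._brute_force(fx)
            assert res.intersection == inter
            assert res.post_qc == keep

    def test_rerun_is_deterministic(self):
        fx = generate_screen_fixture(ScreenFixtureConfig(seed=14))
        a = run_screen(fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols,
                       fx.alias_table, fx.temporal_table, fx.flags_table)
        b = run_screen(fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols,
                       fx.alias_table, fx.temporal_table, fx.flags_table)
        assert a.intersection == b.intersection
        assert a.post_qc == b.post_qc
        assert a.exclusions == b.exclusions

    def test_subset_chain_invariant(self):
        fx = generate_screen_fixture(ScreenFixtureConfig(seed=15))
        res = run_screen(fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols,
                         fx.alias_table, fx.temporal_table, fx.flags_table)
        assert res.post_qc <= res.intersection
        for s in (res.striped, res.surface, res.pairrule):
            assert res.intersection <= s
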