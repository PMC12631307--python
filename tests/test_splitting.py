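"""Splitting strategies and leakage accounting."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from permtask.curation import ENDPOINTS, AggregatedRecord, build_multitask_table
from permtask.splitting import (
    SplitPlan,
    bemis_murcko_scaffold,
    kfold_cv,
    leakage_report,
    modality_folds,
    scaffold_balanced_split,
    scaffold_groups,
    stratified_random_split,
    temporal_rounds,
)


def _rec(smiles, endpoint, mean=1.0, ts=None, modality="unknown"):
    return AggregatedRecord(
        smiles_std=smiles, endpoint=endpoint, mean_log=mean, sd_log=None,
        n_measurements=1, earliest_timestamp=ts, modality=modality,
    )


def _single_endpoint_table(smiles_list, ts=None):
    return build_multitask_table([_rec(s, "Caco2ER", ts=ts) for s in smiles_list])


ALKANES = ["C" * (i + 1) for i in range(1, 60)]  # distinct acyclic SMILES


class TestScaffold:
    def test_ring_framework_extracted(self):
        assert bemis_murcko_scaffold("OCCc1ccccc1") == "c1ccccc1"

    def test_acyclic_is_empty(self):
        assert bemis_murcko_scaffold("CCO") == ""

    def test_para_substituted_benzenes_share_scaffold(self):
        a = bemis_murcko_scaffold("Cc1ccc(O)cc1")
        b = bemis_murcko_scaffold("CCc1ccc(N)cc1")
        assert a == b == "c1ccccc1"

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            bemis_murcko_scaffold("xyz")


class TestStratifiedRandom:
    def test_exact_test_size_single_stratum(self):
        table = _single_endpoint_table(ALKANES[:40])
        plan = stratified_random_split(table, test_frac=0.2, n_repeats=1, seed=0)
        assert len(plan.rounds[0].test) == 8

    def test_per_stratum_rounding(self):
        # two strata: 30 single-endpoint + 10 two-endpoint compounds
        recs = [_rec(s, "Caco2ER") for s in ALKANES[:30]]
        for s in ALKANES[30:40]:
            recs += [_rec(s, "Caco2ER"), _rec(s, "MDCKER")]
        table = build_multitask_table(recs)
        plan = stratified_random_split(table, test_frac=0.2, n_repeats=1, seed=1)
        test_compounds = {s for s, _ in plan.rounds[0].test}
        single = test_compounds & set(ALKANES[:30])
        double = test_compounds & set(ALKANES[30:40])
        assert len(single) == 6 and len(double) == 2

    def test_compounds_move_whole(self, small_table):
        plan = stratified_random_split(small_table, n_repeats=2, seed=3)
        for rnd in plan.rounds:
            assert {s for s, _ in rnd.train} & {s for s, _ in rnd.test} == set()

    def test_determinism(self, small_table):
        a = stratified_random_split(small_table, seed=5).to_frame()
        b = stratified_random_split(small_table, seed=5).to_frame()
        pd.testing.assert_frame_equal(a, b)


class TestScaffoldBalanced:
    def _grouped_table(self):
        # scaffold group sizes [5, 4, 3, 2, 1, 1, 1, 1, 1, 1] over 20 molecules
        cores = ["c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccsc1"]
        subs = ["C", "CC", "CCC", "CCCC", "CCCCC"]
        smiles = []
        for core, size in zip(cores, (5, 4, 3, 2)):
            smiles += [f"{sub}{core}" for sub in subs[:size]]
        singletons = ["C1CCNCC1", "C1CCOCC1", "C1CCCCC1", "C1CCCC1", "C1CC1", "C1CNC1"]
        smiles += [f"C{s}" for s in singletons]
        return _single_endpoint_table(smiles)

    def test_greedy_hand_trace(self):
        table = self._grouped_table()
        sizes = sorted(len(v) for v in scaffold_groups(table.smiles).values())
        assert sizes == [1, 1, 1, 1, 1, 1, 2, 3, 4, 5]
        plan = scaffold_balanced_split(table, test_frac=0.2, n_repeats=3, seed=0)
        for rnd in plan.rounds:
            test_smiles = {s for s, _ in rnd.test}
            assert len(test_smiles) == 4  # whole groups totalling 20% of 20
            tr = {bemis_murcko_scaffold(s) for s, _ in rnd.train}
            te = {bemis_murcko_scaffold(s) for s in test_smiles}
            assert tr & te == set()

    def test_single_scaffold_degenerates_to_empty_test(self):
        table = _single_endpoint_table(["Cc1ccccc1", "CCc1ccccc1", "OCc1ccccc1"])
        plan = scaffold_balanced_split(table, n_repeats=1, seed=0)
        assert len(plan.rounds[0].test) == 0

    def test_scaffold_disjointness_on_synthetic(self, small_table):
        plan = scaffold_balanced_split(small_table, n_repeats=2, seed=9)
        for rnd in plan.rounds:
            tr = {bemis_murcko_scaffold(s) for s, _ in rnd.train}
            te = {bemis_murcko_scaffold(s) for s, _ in rnd.test}
            assert tr & te == set()


class TestTemporal:
    def _toy_table(self):
        # X: endpoint A early, endpoint B late; Y, Z fill the two windows
        recs = [
            _rec("CC", "Caco2ER", ts=date(2020, 1, 1)),
            _rec("CCC", "Caco2ER", ts=date(2020, 2, 1)),
            _rec("CCCC", "Caco2ER", ts=date(2020, 3, 1)),
            _rec("CC", "MDCKER", ts=date(2020, 10, 1)),
            _rec("CCCCC", "Caco2ER", ts=date(2020, 11, 1)),
            _rec("CCCCCC", "Caco2ER", ts=date(2020, 12, 1)),
        ]
        return build_multitask_table(recs)

    def test_leaky_keeps_cross_endpoint_compound(self):
        plan = temporal_rounds(self._toy_table(), 1, mode="leaky", train_fractions=[0.5])
        rnd = plan.rounds[0]
        assert ("CC", "Caco2ER") in rnd.train
        assert ("CC", "MDCKER") in rnd.test

    def test_all_for_one_drops_shared_compound_from_training(self):
        plan = temporal_rounds(
            self._toy_table(), 1, mode="all_for_one", train_fractions=[0.5]
        )
        rnd = plan.rounds[0]
        assert ("CC", "Caco2ER") not in rnd.train
        assert ("CC", "MDCKER") in rnd.test
        assert {s for s, _ in rnd.train} & {s for s, _ in rnd.test} == set()

    def test_schedule_sizes(self):
        table = _single_endpoint_table(ALKANES[:50], ts=None)
        # give each record a distinct date
        recs = [_rec(s, "Caco2ER", ts=date(2020, 1, 1) + pd.Timedelta(days=i).to_pytimedelta())
                for i, s in enumerate(ALKANES[:50])]
        table = build_multitask_table(recs)
        plan = temporal_rounds(table, 5, mode="leaky")
        assert [len(r.train) for r in plan.rounds] == [8, 16, 24, 32, 40]

    def test_nested_and_time_ordered(self, small_table):
        plan = temporal_rounds(small_table, 5, mode="leaky")
        stamps = small_table.timestamps
        prev = frozenset()
        for rnd in plan.rounds:
            assert prev <= rnd.train
            prev = rnd.train
            max_train = max(stamps.at[s, e] for s, e in rnd.train)
            min_test = min(stamps.at[s, e] for s, e in rnd.test)
            assert max_train <= min_test

    def test_missing_timestamps_rejected(self):
        table = _single_endpoint_table(["CC", "CCC"], ts=None)
        with pytest.raises(ValueError, match="without timestamps"):
            temporal_rounds(table, 2, mode="leaky", train_fractions=[0.4, 0.8])


class TestLeakageReport:
    def test_toy_overlap_fifty_percent(self):
        recs = [
            _rec("X", "Caco2ER", ts=date(2020, 1, 1)),
            _rec("X", "MDCKER", ts=date(2020, 1, 2)),
            _rec("Y", "MDCKER", ts=date(2020, 1, 3)),
        ]
        table = build_multitask_table(recs)
        from permtask.splitting import Round

        plan = SplitPlan(
            "manual",
            [Round(1, frozenset({("X", "Caco2ER")}),
                   frozenset({("X", "MDCKER"), ("Y", "MDCKER")}))],
        )
        rep = leakage_report(plan, table).to_frame()
        row = rep[(rep.endpoint == "MDCKER") & (rep["round"] == 1)].iloc[0]
        assert row.train_overlap_pct == pytest.approx(50.0)
        assert row.test_pct == pytest.approx(100.0)

    def test_all_for_one_reports_zero_everywhere(self, small_table):
        plan = temporal_rounds(small_table, 5, mode="all_for_one")
        rep = leakage_report(plan, small_table).to_frame()
        assert (rep.train_overlap_pct == 0.0).all()

    def test_matches_brute_force_oracle_on_random_toys(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            smiles = ALKANES[: int(rng.integers(4, 9))]
            recs = []
            for s in smiles:
                for e in ENDPOINTS:
                    if rng.random() < 0.6:
                        recs.append(_rec(s, e))
            if not recs:
                continue
            table = build_multitask_table(recs)
            cells = sorted(table.observed_cells())
            roles = rng.random(len(cells)) < 0.5
            from permtask.splitting import Round

            train = frozenset(c for c, r in zip(cells, roles) if r)
            test = frozenset(c for c, r in zip(cells, roles) if not r)
            rep = leakage_report(SplitPlan("manual", [Round(1, train, test)]), table)
            train_smiles = {s for s, _ in train}
            for row in rep.to_frame().itertuples():
                ep_cells = [c for c in cells if c[1] == row.endpoint]
                ep_test = {s for s, e in test if e == row.endpoint}
                assert row.test_pct == pytest.approx(100 * len(ep_test) / len(ep_cells))
                expected_overlap = (
                    100 * len(ep_test & train_smiles) / len(ep_test) if ep_test else 0.0
                )
                assert row.train_overlap_pct == pytest.approx(expected_overlap)


class TestFolds:
    def test_kfold_partitions(self):
        table = _single_endpoint_table(ALKANES[:10])
        plan = kfold_cv(table, k=5, seed=0)
        test_sets = [{s for s, _ in r.test} for r in plan.rounds]
        assert all(len(t) == 2 for t in test_sets)
        assert set().union(*test_sets) == set(ALKANES[:10])
        assert sum(len(t) for t in test_sets) == 10

    def test_leave_one_out(self):
        table = _single_endpoint_table(ALKANES[:4])
        plan = kfold_cv(table, k=4, seed=0)
        assert all(len(r.test) == 1 for r in plan.rounds)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            kfold_cv(_single_endpoint_table(ALKANES[:3]), k=5)

    def test_determinism(self, small_table):
        a = kfold_cv(small_table, seed=2).to_frame()
        b = kfold_cv(small_table, seed=2).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_modality_folds_flags_small_groups(self):
        recs = [_rec(s, "Caco2ER", modality="small_molecule") for s in ALKANES[:9]]
        recs.append(_rec(ALKANES[9], "Caco2ER", modality="macrocycle"))
        table = build_multitask_table(recs)
        plan, groups = modality_folds(table, k=5, seed=0)
        assert all(len(r.test) == 2 for r in plan.rounds)
        macro = groups[groups.modality == "macrocycle"]
        assert len(macro) == 1 and bool(macro.small_sample.iloc[0])


class TestPlanContracts:
    def test_train_test_cell_clash_rejected(self):
        from permtask.splitting import Round

        with pytest.raises(ValueError, match="both train and test"):
            SplitPlan(
                "manual",
                [Round(1, frozenset({("C", "Caco2ER")}), frozenset({("C", "Caco2ER")}))],
            )

    def test_plan_csv_round_trip(self, small_table):
        plan = kfold_cv(small_table, k=3, seed=1)
        frame = plan.to_frame()
        rebuilt = SplitPlan.from_frame(frame, strategy=plan.strategy)
        assert [r.train for r in rebuilt.rounds] == [r.train for r in plan.rounds]
        assert [r.test for r in rebuilt.rounds] == [r.test for r in plan.rounds]
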