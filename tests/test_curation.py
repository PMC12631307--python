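"""Curation: standardization, aggregation, noise model, outliers, table."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from permtask.curation import (
    ENDPOINTS,
    AggregatedRecord,
    InsufficientDataError,
    RawMeasurement,
    SigmaModel,
    StandardizationError,
    aggregate,
    build_multitask_table,
    coverage_summary,
    curate,
    efflux_ratio,
    fit_sigma_model,
    flag_outliers,
    ingest_external,
    parse_bounded_value,
    standardize_structure,
    to_log,
)


class TestStandardize:
    @pytest.mark.parametrize(
        "a,b",
        [("C1=CC=CC=C1", "c1ccccc1"), ("OCC", "CCO"), ("CC(=O)[O-].[Na+]", "CC(=O)O")],
    )
    def test_equivalent_inputs_map_to_one_canonical_form(self, a, b):
        assert standardize_structure(a) == standardize_structure(b)

    @pytest.mark.parametrize("s", ["c1ccccc1O", "NC(Cc1ccccc1)C(=O)O", "CCO"])
    def test_idempotent(self, s):
        once = standardize_structure(s)
        assert standardize_structure(once) == once

    @pytest.mark.parametrize("bad", ["not_a_smiles", "", "C1CC"])
    def test_unparsable_rejected(self, bad):
        with pytest.raises(StandardizationError):
            standardize_structure(bad)


class TestScalarOps:
    @pytest.mark.parametrize(
        "raw,expected",
        [("<0.1", (0.1, "lower_bound")), (">50", (50.0, "upper_bound")),
         ("3.2", (3.2, "none")), (7, (7.0, "none"))],
    )
    def test_parse_bounded_value(self, raw, expected):
        assert parse_bounded_value(raw) == expected

    def test_parse_bounded_value_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_bounded_value("<abc")

    def test_to_log(self):
        assert to_log(100) == pytest.approx(2.0)
        assert to_log(1) == 0.0
        with pytest.raises(ValueError):
            to_log(-1e-9)

    @pytest.mark.parametrize("ba,ab,er", [(10, 5, 2.0), (5, 5, 1.0), (0.3, 0.1, 3.0)])
    def test_efflux_ratio(self, ba, ab, er):
        assert efflux_ratio(ba, ab) == pytest.approx(er)

    def test_efflux_ratio_domain(self):
        with pytest.raises(ValueError):
            efflux_ratio(1.0, 0.0)


def _meas(smiles, endpoint, log_value, **kw):
    return RawMeasurement(smiles=smiles, endpoint=endpoint, value=10.0 ** log_value, **kw)


class TestAggregate:
    def test_replicates_mean_and_sample_sd(self):
        ms = [_meas("CCO", "Caco2ER", v) for v in (1.0, 1.2, 1.4)]
        (rec,) = aggregate(ms)
        assert rec.mean_log == pytest.approx(1.2)
        assert rec.sd_log == pytest.approx(0.2)
        assert rec.n_measurements == 3

    def test_singleton_has_no_sd(self):
        (rec,) = aggregate([_meas("CCO", "Caco2ER", 0.5)])
        assert rec.mean_log == pytest.approx(0.5)
        assert rec.sd_log is None and rec.n_measurements == 1

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        smiles = ["CCO", "CCN", "CCC"]
        ms = [
            _meas(smiles[rng.integers(3)], ENDPOINTS[rng.integers(4)],
                  float(rng.normal()), timestamp=date(2020, 1, 1 + int(rng.integers(28))))
            for _ in range(60)
        ]
        records = aggregate(ms)
        frame = pd.DataFrame(
            {"s": [m.smiles for m in ms], "e": [m.endpoint for m in ms],
             "v": [math.log10(m.value) for m in ms],
             "t": [m.timestamp for m in ms]}
        )
        oracle = frame.groupby(["s", "e"]).agg(
            mean=("v", "mean"), sd=("v", lambda x: x.std(ddof=1)),
            n=("v", "size"), first=("t", "min"),
        )
        assert len(records) == len(oracle)
        for rec in records:
            row = oracle.loc[(rec.smiles_std, rec.endpoint)]
            assert rec.mean_log == pytest.approx(row["mean"])
            assert rec.n_measurements == row["n"]
            assert rec.earliest_timestamp == row["first"]
            if rec.n_measurements > 1:
                assert rec.sd_log == pytest.approx(row["sd"])
        # count conservation
        assert sum(r.n_measurements for r in records) == len(ms)


def _rec(smiles, endpoint, mean, sd, n, **kw):
    return AggregatedRecord(
        smiles_std=smiles, endpoint=endpoint, mean_log=mean, sd_log=sd,
        n_measurements=n, **kw,
    )


class TestSigmaModel:
    def test_collinear_points_recovered_exactly(self):
        recs = [_rec(f"C{'C' * i}O", "Caco2ER", m, s, 2)
                for i, (m, s) in enumerate([(0, 0.3), (1, 0.2), (2, 0.1)])]
        model = fit_sigma_model(recs, "Caco2ER")
        assert model.intercept == pytest.approx(0.3)
        assert model.slope == pytest.approx(-0.1)
        assert model.n_fit == 3

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 0.2 - 0.05 * x + rng.normal(scale=0.03, size=25)
        recs = [_rec(f"smi{i}", "MDCKER", float(xi), float(abs(yi)) + 0.01, 3)
                for i, (xi, yi) in enumerate(zip(x, y))]
        model = fit_sigma_model(recs, "MDCKER")
        X = np.column_stack([np.ones(25), x])
        yy = np.array([r.sd_log for r in recs])
        beta = np.linalg.solve(X.T @ X, X.T @ yy)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_insufficient_data(self):
        recs = [_rec("CCO", "Caco2ER", 0.0, 0.1, 2), _rec("CCN", "Caco2ER", 1.0, 0.2, 2),
                _rec("CCC", "Caco2ER", 2.0, None, 1)]
        with pytest.raises(InsufficientDataError):
            fit_sigma_model(recs, "Caco2ER")

    def test_only_replicated_records_enter_fit(self):
        base = [_rec(f"C{'C' * i}O", "Caco2ER", m, s, 2)
                for i, (m, s) in enumerate([(0, 0.3), (1, 0.2), (2, 0.1)])]
        with_singleton = base + [_rec("CCCCN", "Caco2ER", 5.0, None, 1)]
        a, b = fit_sigma_model(base, "Caco2ER"), fit_sigma_model(with_singleton, "Caco2ER")
        assert (a.intercept, a.slope, a.n_fit) == (b.intercept, b.slope, b.n_fit)


class TestFlagOutliers:
    model = SigmaModel(intercept=0.3, slope=-0.1, endpoint="Caco2ER", n_fit=10)

    def test_hand_rule(self):
        hot = _rec("CCO", "Caco2ER", 1.0, 0.5, 2)     # 0.5 > 2 * 0.2
        cold = _rec("CCN", "Caco2ER", 1.0, 0.3, 2)    # 0.3 <= 0.4
        lone = _rec("CCC", "Caco2ER", 1.0, None, 1)
        flagged = flag_outliers([hot, cold, lone], self.model, k=2)
        assert flagged == {("CCO", "Caco2ER")}

    def test_singletons_never_flagged(self):
        recs = [_rec(f"smi{i}", "Caco2ER", 99.0, None, 1) for i in range(5)]
        assert flag_outliers(recs, self.model) == set()

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(40):
            n = int(rng.integers(1, 4))
            recs.append(_rec(f"smi{i}", "Caco2ER", float(rng.normal(1, 1)),
                             float(rng.uniform(0, 0.8)) if n > 1 else None, n))
        k, floor = 2.0, 0.01
        flagged = flag_outliers(recs, self.model, k=k, sigma_floor=floor)
        oracle = {
            (r.smiles_std, r.endpoint)
            for r in recs
            if r.n_measurements >= 2
            and r.sd_log > k * max(floor, self.model.intercept + self.model.slope * r.mean_log)
        }
        assert flagged == oracle


class TestMultitaskTable:
    def test_pivot_against_brute_force(self):
        recs = [_rec("CCO", "Caco2ER", 1.0, None, 1), _rec("CCO", "MDCKER", 0.5, None, 1),
                _rec("CCN", "Caco2Papp", 1.5, None, 1)]
        table = build_multitask_table(recs)
        assert len(table) == 2
        assert sorted(table.mask.sum(axis=1)) == [1, 2]
        assert table.values.at["CCO", "MDCKER"] == pytest.approx(0.5)
        assert not table.mask.at["CCN", "Caco2ER"]
        assert list(table.values.columns) == list(ENDPOINTS)

    def test_empty_input(self):
        assert len(build_multitask_table([])) == 0

    def test_order_invariance(self):
        recs = [_rec(f"C{'C' * i}O", ENDPOINTS[i % 4], float(i) / 7, None, 1)
                for i in range(8)]
        a = build_multitask_table(recs)
        b = build_multitask_table(list(reversed(recs)))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_duplicate_records_rejected(self):
        recs = [_rec("CCO", "Caco2ER", 1.0, None, 1), _rec("CCO", "Caco2ER", 2.0, None, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            build_multitask_table(recs)

    def test_coverage_summary(self):
        recs = (
            [_rec("C", "Caco2ER", 1.0, None, 1)]
            + [_rec("CC", "Caco2ER", 1.0, None, 1)]
            + [_rec("CCC", e, 1.0, None, 1) for e in ENDPOINTS[:2]]
            + [_rec("CCCC", e, 1.0, None, 1) for e in ENDPOINTS]
        )
        summary = coverage_summary(build_multitask_table(recs))
        assert summary == {1: 0.5, 2: 0.25, 3: 0.0, 4: 0.25}
        assert sum(summary.values()) == pytest.approx(1.0)

    def test_long_frame_round_trip(self, small_table):
        rebuilt = type(small_table).from_long_frame(small_table.to_long_frame())
        pd.testing.assert_frame_equal(rebuilt.values, small_table.values)
        pd.testing.assert_frame_equal(rebuilt.mask, small_table.mask)


class TestCuratePipeline:
    def test_rejects_bad_smiles_with_reason(self):
        ms = [_meas("CCO", "Caco2ER", 1.0),
              RawMeasurement("not_a_smiles", "Caco2ER", 10.0)]
        result = curate(ms)
        assert len(result.rejected) == 1
        assert len(result.records) == 1

    def test_idempotent_on_curated_output(self, small_curated):
        table = small_curated.table
        again = curate(table.to_measurements(), standardize=False)
        pd.testing.assert_frame_equal(again.table.values, table.values)
        assert again.outliers == set()

    def test_count_conservation(self, small_dataset):
        ms = small_dataset.measurements
        records = aggregate(ms)
        assert sum(r.n_measurements for r in records) == len(ms)


class TestIngestExternal:
    def test_sentinel_dropped_positive_retained(self):
        frame = pd.DataFrame(
            {"SMILES": ["CCO", "CCN"], "Permeability": [-10e-10, 5e-6]}
        )
        out = ingest_external(frame, "cycpeptmpdb")
        assert len(out) == 1
        assert out[0].smiles == "CCN"
        assert out[0].value == pytest.approx(5.0)  # normalized to 1e-6 cm/s
        assert out[0].endpoint == "Caco2Papp"

    def test_empty_result_ok(self):
        frame = pd.DataFrame({"SMILES": ["CCO"], "Permeability": [-10e-10]})
        assert ingest_external(frame, "cycpeptmpdb") == []

    def test_unknown_source_is_config_error(self):
        with pytest.raises(ValueError, match="unknown external source"):
            ingest_external(pd.DataFrame(), "pubchem")

    def test_nmmpdb_layout_uses_endpoint_column(self):
        frame = pd.DataFrame(
            {"SMILES": ["CCO"], "Value": [2.5], "Endpoint": ["MDCKER"]}
        )
        (m,) = ingest_external(frame, "nmmpdb")
        assert m.endpoint == "MDCKER" and m.value == pytest.approx(2.5)
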