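"""SGA residual-analysis pipeline stages against hand oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genebuffer import (
    InsufficientDataError,
    NeutralityModel,
    SchemaError,
    apply_filters,
    compare_distributions,
    compute_expectations,
    compute_qvalues,
    hybrid_expectation,
    load_crosses,
    standardized_residuals,
    summarize_residuals,
)
from genebuffer.simulate import SimulationSpec, generate


class TestLoadCrosses:
    def test_incomplete_rows_dropped_and_counted(self, tmp_path):
        csv = tmp_path / "crosses.csv"
        rows = ["query_id,array_id,f_query,f_array,f_double,sd_double"]
        for i in range(6):
            f = "" if i == 3 else "0.5"
            rows.append(f"Q{i},A{i},{f},0.8,0.4,0.05")
        csv.write_text("\n".join(rows))
        table, n_dropped = load_crosses(csv)
        assert len(table) == 5 and n_dropped == 1

    def test_missing_column_lists_headers(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text("foo,bar\n1,2\n")
        with pytest.raises(SchemaError, match="foo"):
            load_crosses(csv, column_map={"nope": "f_query"})

    def test_synthetic_round_trip(self, tmp_path):
        table, _ = generate(SimulationSpec(n_crosses=50, seed=3))
        path = tmp_path / "synthetic.csv"
        table.to_csv(path, index=False)
        loaded, n_dropped = load_crosses(path)
        assert n_dropped == 0
        pd.testing.assert_frame_equal(loaded, table)

    def test_custom_column_map(self, tmp_path):
        csv = tmp_path / "mapped.tsv"
        csv.write_text("q\ta\tfq\tfa\tfd\tsd\nQ1\tA1\t0.5\t0.8\t0.4\t0.05\n")
        table, _ = load_crosses(csv, column_map={
            "q": "query_id", "a": "array_id", "fq": "f_query",
            "fa": "f_array", "fd": "f_double", "sd": "sd_double"},
            delimiter="\t")
        assert table.loc[0, "f_query"] == 0.5


class TestExpectations:
    def test_worked_values(self):
        df = pd.DataFrame({"f_query": [0.7, 1.0, 0.9],
                           "f_array": [0.5, 0.6, 0.9],
                           "f_double": [0.3, 0.6, 0.8],
                           "sd_double": [0.05] * 3})
        out = compute_expectations(df)
        assert out["f_expected_serial"].tolist() == pytest.approx([0.35, 0.6, 0.81])
        assert out["f_expected_parallel"].tolist() == pytest.approx(
            [0.4118, 0.6, 0.8182], abs=5e-4)

    def test_nonpositive_fitness_flagged_not_failed(self):
        df = pd.DataFrame({"f_query": [0.0, 0.5], "f_array": [0.5, 0.5],
                           "f_double": [0.1, 0.2], "sd_double": [0.05, 0.05]})
        out = compute_expectations(df)
        assert math.isnan(out["f_expected_parallel"][0])
        assert out["f_expected_serial"][0] == 0.0


class TestQValues:
    def test_exact_fit_gives_p_one(self):
        df = compute_expectations(pd.DataFrame({
            "f_query": [0.5], "f_array": [0.8],
            "f_double": [0.4], "sd_double": [0.05]}))
        out = compute_qvalues(df, "serial")
        assert out["p_serial"][0] == pytest.approx(1.0)
        assert out["q_serial"][0] == pytest.approx(1.0)

    def test_z_1p96_gives_p_05(self):
        df = compute_expectations(pd.DataFrame({
            "f_query": [0.5], "f_array": [0.8],
            "f_double": [0.4 + 1.959964 * 0.05], "sd_double": [0.05]}))
        out = compute_qvalues(df, "serial")
        assert out["p_serial"][0] == pytest.approx(0.05, abs=1e-6)

    def test_bh_hand_oracle(self):
        # four crosses with p = 0.01, 0.02, 0.03, 0.04 -> all q = 0.04
        z = stats.norm.isf(np.array([0.01, 0.02, 0.03, 0.04]) / 2)
        df = compute_expectations(pd.DataFrame({
            "f_query": [0.5] * 4, "f_array": [0.8] * 4,
            "f_double": 0.4 + z * 0.05, "sd_double": [0.05] * 4}))
        out = compute_qvalues(df, "serial")
        assert out["q_serial"].tolist() == pytest.approx([0.04] * 4, abs=1e-9)

    def test_bh_monotone_and_capped(self):
        rng = np.random.default_rng(5)
        df = compute_expectations(pd.DataFrame({
            "f_query": rng.uniform(0.2, 0.9, 200),
            "f_array": rng.uniform(0.2, 0.9, 200),
            "f_double": rng.uniform(0.0, 1.0, 200),
            "sd_double": np.full(200, 0.05)}))
        out = compute_qvalues(df, "serial").sort_values("p_serial")
        q = out["q_serial"].to_numpy()
        assert (np.diff(q) >= -1e-12).all() and (q <= 1).all()
        assert (out["q_serial"] >= out["p_serial"] - 1e-12).all()

    def test_bad_sd_excluded(self):
        df = compute_expectations(pd.DataFrame({
            "f_query": [0.5, 0.5], "f_array": [0.8, 0.8],
            "f_double": [0.4, 0.4], "sd_double": [0.0, 0.05]}))
        out = compute_qvalues(df, "serial")
        assert math.isnan(out["q_serial"][0]) and not math.isnan(out["q_serial"][1])


class TestFilters:
    def _table(self):
        df = pd.DataFrame({
            "f_query": [0.5, 0.05, 0.95, 0.5, 0.5, 0.2, 0.8, 0.3, 0.6, 0.7],
            "f_array": [0.5, 0.5, 0.5, 0.05, 0.95, 0.4, 0.6, 0.7, 0.2, 0.5],
            "f_double": [0.25] * 10,
            "sd_double": [0.3] * 10,
        })
        df = compute_expectations(df)
        df = compute_qvalues(df, "serial")
        return compute_qvalues(df, "parallel")

    def test_hand_filter_oracle(self):
        df = self._table()
        in_band = (df["f_query"].between(0.1, 0.9)
                   & df["f_array"].between(0.1, 0.9))
        q_ok = (df["q_serial"] > 0.5) & (df["q_parallel"] > 0.5)
        expected = int((in_band & q_ok).sum())
        assert len(apply_filters(df)) == expected
        assert expected > 0  # fixture actually exercises the filter

    def test_band_is_closed_interval(self):
        df = pd.DataFrame({"f_query": [0.1, 0.9], "f_array": [0.9, 0.1],
                           "f_double": [0.09, 0.09], "sd_double": [0.3, 0.3]})
        df = compute_expectations(df)
        assert len(apply_filters(df, q_min=None)) == 2

    def test_empty_input(self):
        df = self._table().iloc[:0]
        assert len(apply_filters(df)) == 0


class TestStandardizedResiduals:
    def test_hand_arithmetic_fixture(self, five_record_table):
        df = compute_expectations(five_record_table)
        res = standardized_residuals(df, "serial")
        s = math.sqrt(0.1 / 3)
        assert s == pytest.approx(0.1826, abs=5e-5)
        assert res == pytest.approx(
            np.array([0.1, -0.1, 0.2, 0.0, -0.2]) / s)
        assert res == pytest.approx([0.548, -0.548, 1.095, 0.0, -1.095], abs=5e-4)

    def test_exact_fit_gives_zero_residuals(self):
        fq = [0.5, 0.6, 0.7]
        df = compute_expectations(pd.DataFrame({
            "f_query": fq, "f_array": [0.8] * 3,
            "f_double": [f * 0.8 for f in fq], "sd_double": [0.05] * 3}))
        assert standardized_residuals(df, "serial").tolist() == [0, 0, 0]

    def test_sign_pattern_preserved(self, five_record_table):
        df = compute_expectations(five_record_table)
        raw = (df["f_double"] - df["f_expected_serial"]).to_numpy()
        assert np.array_equal(np.sign(standardized_residuals(df, "serial")),
                              np.sign(raw))

    def test_too_few_records(self, five_record_table):
        df = compute_expectations(five_record_table.iloc[:2])
        with pytest.raises(InsufficientDataError):
            standardized_residuals(df, "serial")

    def test_serial_residual_never_below_parallel(self):
        """Parallel expectation dominates serial on (0,1]^2, so per cross
        the serial residual is the larger of the two."""
        table, _ = generate(SimulationSpec(n_crosses=500, seed=9))
        df = compute_expectations(table)
        raw_serial = df["f_double"] - df["f_expected_serial"]
        raw_parallel = df["f_double"] - df["f_expected_parallel"]
        assert (raw_serial >= raw_parallel - 1e-12).all()


class TestHybrid:
    def test_larger_q_wins_and_ties_go_serial(self):
        df = pd.DataFrame({
            "f_expected_serial": [0.35, 0.35, 0.35],
            "f_expected_parallel": [0.41, 0.41, 0.41],
            "q_serial": [0.9, 0.2, 0.5],
            "q_parallel": [0.3, 0.8, 0.5],
        })
        out = hybrid_expectation(df)
        assert out["hybrid_model"].tolist() == ["serial", "parallel", "serial"]
        assert out["f_expected_hybrid"].tolist() == [0.35, 0.41, 0.35]

    def test_noise_free_parallel_data_selects_parallel(self):
        table, truth = generate(SimulationSpec(
            n_crosses=300, frac_parallel=1.0, noise_sd=1e-6, seed=2))
        df = compute_expectations(table)
        df = compute_qvalues(df, "serial")
        df = compute_qvalues(df, "parallel")
        out = hybrid_expectation(df)
        assert (out["hybrid_model"] == "parallel").all()


class TestSummaries:
    def test_symmetric_fixture(self):
        s = summarize_residuals(np.array([-1.0, 0.0, 1.0]))
        assert s.median == 0 and s.mean == 0
        assert s.frac_le_zero == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_residuals(np.array([]))

    def test_frac_le_zero_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(1)
        res = rng.normal(0.3, 1.0, 500)
        a = summarize_residuals(res).frac_le_zero
        b = summarize_residuals(res / res.std()).frac_le_zero
        assert a == b


class TestCompareDistributions:
    def test_sample_vs_itself_is_maximal(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=200)
        assert compare_distributions(a, a) > 0.99

    def test_known_separation(self):
        rng = np.random.default_rng(8)
        assert compare_distributions(rng.normal(0, 1, 500),
                                     rng.normal(2, 1, 500)) < 1e-6

    def test_null_simulation(self):
        rng = np.random.default_rng(12)
        assert compare_distributions(rng.normal(0, 1, 500),
                                     rng.normal(0, 1, 500)) > 0.01

    def test_identical_constants_warn_not_crash(self, caplog):
        assert compare_distributions(np.ones(5), np.ones(5)) == 1.0
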