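from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqpanel import (
    SampleSheet,
    SimConfig,
    bh_adjust,
    differential_table,
    generate_cq_dataset,
    global_mean_normalize,
    group_effect,
    select_candidates,
    two_sample_t,
)
from cqpanel.differential import DiffExpTable

from helpers import bh_brute_force, student_t_brute_force


class TestGroupEffect:
    def test_hand_arithmetic(self):
        eff = group_effect([1.0, 1.2, 0.8], [-1.0, -0.8, -1.2])
        assert eff.mean_dcq_h == pytest.approx(1.0)
        assert eff.mean_dcq_p == pytest.approx(-1.0)
        assert eff.ddcq == pytest.approx(-2.0)
        assert eff.neg_ddcq == pytest.approx(2.0)
        assert eff.direction == "up"

    def test_identical_groups(self):
        eff = group_effect([1.0, 2.0], [1.0, 2.0])
        assert eff.ddcq == 0.0
        assert eff.direction == "none"

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=4)
        assert group_effect(a, b).neg_ddcq == -group_effect(b, a).neg_ddcq

    def test_means_over_detected_only(self):
        eff = group_effect([1.0, np.nan, 3.0], [5.0])
        assert eff.mean_dcq_h == 2.0
        assert eff.n_healthy == 2 and eff.n_perio == 1

    def test_empty_group_not_analyzable(self):
        eff = group_effect([], [1.0])
        assert not eff.analyzable
        assert np.isnan(eff.ddcq)


class TestTwoSampleT:
    def test_student_closed_form(self):
        t, p = two_sample_t([1, 2, 3], [3, 4, 5], variant="student")
        assert t == pytest.approx(-2.449, abs=1e-3)
        assert t == pytest.approx(student_t_brute_force([1, 2, 3], [3, 4, 5]), abs=1e-12)
        # df = 4 for the pooled test
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=4), abs=1e-12)

    def test_identical_vectors(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_welch_equals_student_for_equal_variances(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5]
        tw, _ = two_sample_t(a, b, variant="welch")
        ts, _ = two_sample_t(a, b, variant="student")
        assert tw == pytest.approx(ts, abs=1e-6)

    def test_insufficient_n_flagged(self):
        t, p = two_sample_t([1.0], [1.0, 2.0])
        assert np.isnan(t) and np.isnan(p)

    def test_zero_variance_equal_means_undefined(self):
        t, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(t) and np.isnan(p)

    def test_zero_variance_unequal_means_warns_limiting_p(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            t, p = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and np.isinf(t)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            two_sample_t([1, 2], [3, 4], variant="mannwhitney")


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_missing_p_returned_missing(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        # m = 2 for the non-missing entries
        assert q[0] == pytest.approx(0.02)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        if seed % 3 == 0:  # exercise ties
            p = np.round(p, 1)
        assert np.allclose(bh_adjust(p), bh_brute_force(p.tolist()), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_contract_properties(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


def _diff_from_matrix(matrix: pd.DataFrame, n_h: int, n_p: int, **kw) -> DiffExpTable:
    from cqpanel import CqTable

    samples = [f"H{i}" for i in range(n_h)] + [f"P{i}" for i in range(n_p)]
    matrix = matrix.set_axis(samples, axis=1)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["healthy"] * n_h + ["periodontitis"] * n_p,
                "set_id": "set1",
            }
        )
    )
    norm = global_mean_normalize(CqTable(matrix))
    return differential_table(norm, sheet, **kw)


class TestDifferentialTable:
    def _random_table(self, seed=0, n=30, n_h=4, n_p=4):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            rng.uniform(20, 35, size=(n, n_h + n_p)),
            index=[f"hsa-m{i}" for i in range(n)],
        )
        return _diff_from_matrix(frame, n_h, n_p)

    def test_columns_and_sorting(self):
        table = self._random_table()
        df = table.df
        assert list(df.columns)[:6] == [
            "n_healthy",
            "n_perio",
            "mean_dcq_h",
            "mean_dcq_p",
            "ddcq",
            "neg_ddcq",
        ]
        q = df["q_value"].to_numpy()
        assert (np.diff(q[~np.isnan(q)]) >= 0).all()

    def test_neg_ddcq_is_exact_negation(self):
        df = self._random_table().df
        assert (df["neg_ddcq"] == -df["ddcq"]).all()

    def test_matches_scalar_path_row_by_row(self):
        table = self._random_table(seed=5)
        # re-derive each row with the scalar operations
        for m in table.df.index[:10]:
            row = table.df.loc[m]
            assert row["ddcq"] == pytest.approx(row["mean_dcq_p"] - row["mean_dcq_h"])

    def test_min_n_descriptive_only(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            rng.uniform(20, 30, size=(3, 6)), index=["hsa-a", "hsa-b", "hsa-c"]
        )
        frame.iloc[0, 3:5] = np.nan  # only one detected periodontitis value
        table = _diff_from_matrix(frame, 3, 3)
        row = table.df.loc["hsa-a"]
        assert row["n_perio"] == 1
        assert np.isnan(row["p_value"]) and np.isnan(row["q_value"])
        assert not np.isnan(row["ddcq"])  # effect still reported

    def test_welch_vs_student_config(self):
        t_w = self._random_table(seed=7)
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(
            rng.uniform(20, 35, size=(30, 8)), index=[f"hsa-m{i}" for i in range(30)]
        )
        t_s = _diff_from_matrix(frame, 4, 4, t_variant="student")
        assert t_w.t_variant == "welch" and t_s.t_variant == "student"
        assert not np.allclose(
            t_w.df["p_value"].to_numpy(), t_s.df["p_value"].to_numpy()
        )

    def test_available_case_matches_scalar_oracle(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            rng.uniform(20, 35, size=(12, 10)), index=[f"hsa-m{i}" for i in range(12)]
        )
        mask = rng.random(frame.shape) < 0.2
        frame = frame.mask(mask)
        # keep at least one detected per sample for normalization
        frame.iloc[0, :] = rng.uniform(20, 35, size=10)
        table = _diff_from_matrix(frame, 5, 5)
        from cqpanel import CqTable

        norm = global_mean_normalize(CqTable(frame.set_axis(table_samples := [f"H{i}" for i in range(5)] + [f"P{i}" for i in range(5)], axis=1)))
        for m in table.df.index:
            h = norm.delta_cq.loc[m, table_samples[:5]].to_numpy()
            p = norm.delta_cq.loc[m, table_samples[5:]].to_numpy()
            t, pv = two_sample_t(h, p)
            if np.isnan(pv):
                assert np.isnan(table.df.loc[m, "p_value"])
            else:
                assert table.df.loc[m, "t_stat"] == pytest.approx(t, abs=1e-10)
                assert table.df.loc[m, "p_value"] == pytest.approx(pv, abs=1e-10)


class TestSelectCandidates:
    def _table(self, records):
        df = pd.DataFrame(records).set_index("mirna_id")
        for col in ("n_healthy", "n_perio", "mean_dcq_h", "mean_dcq_p", "t_stat", "p_value"):
            df[col] = df.get(col, 0.0)
        df["ddcq"] = -df["neg_ddcq"]
        df["direction"] = np.where(df["neg_ddcq"] > 0, "up", "down")
        df["passes"] = False
        from cqpanel.differential import _DIFF_COLUMNS

        return DiffExpTable(df[_DIFF_COLUMNS])

    def test_criteria(self):
        table = self._table(
            [
                {"mirna_id": "hsa-in-up", "q_value": 0.04, "neg_ddcq": 1.2},
                {"mirna_id": "hsa-boundary-effect", "q_value": 0.04, "neg_ddcq": 1.0},
                {"mirna_id": "hsa-boundary-q", "q_value": 0.05, "neg_ddcq": 3.0},
                {"mirna_id": "hsa-not-sig", "q_value": 0.06, "neg_ddcq": 3.0},
                {"mirna_id": "hsa-in-down", "q_value": 0.01, "neg_ddcq": -2.0},
            ]
        )
        up, down = select_candidates(table, 0.05, 1.0)
        assert up.members == ("hsa-in-up",)
        assert down.members == ("hsa-in-down",)

    def test_disjoint(self):
        rng = np.random.default_rng(9)
        table = self._table(
            [
                {
                    "mirna_id": f"hsa-m{i}",
                    "q_value": rng.uniform(0, 0.1),
                    "neg_ddcq": rng.normal(0, 2),
                }
                for i in range(50)
            ]
        )
        up, down = select_candidates(table)
        assert not set(up.members) & set(down.members)

    def test_label_swap_maps_up_to_down(self):
        cfg = SimConfig(n_mirna=60, n_up=5, n_down=5, seed=10)
        table, sheet, _ = generate_cq_dataset(cfg)
        norm = global_mean_normalize(table)
        fwd = differential_table(norm, sheet)
        swapped = SampleSheet(
            sheet.data.reset_index().assign(
                group=lambda d: d["group"].map(
                    {"healthy": "periodontitis", "periodontitis": "healthy"}
                )
            )
        )
        rev = differential_table(norm, swapped)
        up_f, down_f = select_candidates(fwd)
        up_r, down_r = select_candidates(rev)
        assert set(up_f.members) == set(down_r.members)
        assert set(down_f.members) == set(up_r.members)


class TestSimulationCalibration:
    def test_null_type_i_rate(self):
        # no spiked effects: p < 0.05 rate should be near nominal
        rates = []
        for seed in range(30):
            cfg = SimConfig(
                n_mirna=150, n_up=0, n_down=0, n_refs=0, seed=seed,
                baseline_range=(20.0, 34.0),
            )
            table, sheet, _ = generate_cq_dataset(cfg)
            norm = global_mean_normalize(table)
            diff = differential_table(norm, sheet)
            p = diff.df["p_value"].dropna()
            rates.append((p < 0.05).mean())
        rate = float(np.mean(rates))
        assert 0.03 < rate < 0.07

    def test_power_at_spiked_effect(self):
        cfg = SimConfig(
            n_mirna=150,
            n_up=10,
            n_down=10,
            effect_cycles=2.0,
            noise_sd=0.5,
            baseline_range=(20.0, 34.0),
            seed=77,
        )
        table, sheet, truth = generate_cq_dataset(cfg)
        norm = global_mean_normalize(table)
        diff = differential_table(norm, sheet)
        up, down = select_candidates(diff)
        from cqpanel import score_recovery

        rec = score_recovery(truth, up, down)
        assert rec["sensitivity_up"] >= 0.95
        assert rec["sensitivity_down"] >= 0.95
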