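"""Endpoint computation, summary statistics and NOAEL/LOAEL calls."""

import numpy as np
import pytest
from scipy import stats

from bayesbmc.data import (
    DoseGroupSummary,
    DoseResponseDataset,
    WellCounts,
    anova_lsd,
    compute_cm,
    compute_cma,
    loael_majority,
    read_replicate_csv,
    read_summary_csv,
    summarize_groups,
)


def well(dose=0.0, dead=(0, 0, 0, 0, 0), n=40, hatched=30, malformed=0, rid="r1"):
    return WellCounts(dose, rid, n, tuple(dead), hatched, malformed)


class TestWellCounts:
    def test_rejects_decreasing_cumulative_deaths(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            well(dead=(3, 2, 2, 2, 2))

    def test_rejects_malformed_exceeding_hatched(self):
        with pytest.raises(ValueError):
            well(hatched=5, malformed=6)

    def test_rejects_deaths_exceeding_embryos(self):
        with pytest.raises(ValueError):
            well(dead=(0, 0, 0, 0, 41))


class TestCumulativeMortality:
    @pytest.mark.parametrize(
        "dead5, expected", [(0, 0.0), (20, 50.0), (40, 100.0)]
    )
    def test_day5_fraction(self, dead5, expected):
        w = well(dead=(0, 0, 0, 0, dead5), hatched=0)
        assert compute_cm([w], 5) == pytest.approx(expected)

    def test_total_kill_at_first_day_is_100(self):
        # the 300 mg/L groups in the bundled table: every embryo dead at 1 dpf
        w = well(dose=300.0, dead=(40, 40, 40, 40, 40), hatched=0)
        assert compute_cm([w], 1) == pytest.approx(100.0)

    def test_nondecreasing_in_day(self):
        rng = np.random.default_rng(7)
        deads = np.sort(rng.integers(0, 41, size=(20, 5)), axis=1)
        wells = [well(dead=tuple(d), hatched=0, rid=f"r{i}") for i, d in enumerate(deads)]
        cms = np.array([compute_cm(wells, day) for day in range(1, 6)])
        assert np.all(np.diff(cms, axis=0) >= 0)

    def test_rejects_bad_day_and_empty(self):
        with pytest.raises(ValueError):
            compute_cm([well()], 6)
        with pytest.raises(ValueError):
            compute_cm([], 3)


class TestMalformationRate:
    @pytest.mark.parametrize("malformed, expected", [(0, 0.0), (15, 50.0)])
    def test_fraction_of_hatched(self, malformed, expected):
        w = well(hatched=30, malformed=malformed)
        assert compute_cma([w]) == pytest.approx(expected)

    def test_zero_hatched_excluded_with_warning(self):
        ws = [well(hatched=0, rid="r1"), well(hatched=10, malformed=5, rid="r2")]
        with pytest.warns(UserWarning, match="zero hatched"):
            out = compute_cma(ws)
        assert out == pytest.approx([50.0])

    def test_all_zero_hatched_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_cma([well(hatched=0)])


class TestSummarizeGroups:
    def test_constant_replicates(self):
        ds = summarize_groups({0.0: [10, 10, 10], 1.0: [20, 20, 20], 2.0: [1, 1, 1]})
        assert ds.groups[0].mean == 10 and ds.groups[0].sd == 0

    def test_sample_sd_uses_n_minus_1(self):
        ds = summarize_groups({0.0: [0, 100], 1.0: [1, 2], 2.0: [3, 4]})
        assert ds.groups[0].mean == pytest.approx(50.0)
        assert ds.groups[0].sd == pytest.approx(70.71, abs=0.01)

    def test_single_replicate_warns_and_zeroes_sd(self):
        with pytest.warns(UserWarning, match="single replicate"):
            ds = summarize_groups({0.0: [25], 1.0: [1, 2], 2.0: [3, 4]})
        assert ds.groups[0].sd == 0.0


class TestDatasetValidation:
    def test_requires_control_and_increasing_doses(self):
        g = lambda d, m: DoseGroupSummary(d, 6, m, 1.0)
        with pytest.raises(ValueError, match="control"):
            DoseResponseDataset("x", (g(1, 5), g(2, 6), g(3, 7)))
        with pytest.raises(ValueError, match="increasing"):
            DoseResponseDataset("x", (g(0, 5), g(2, 6), g(2, 7)))
        with pytest.raises(ValueError, match="3 dose groups"):
            DoseResponseDataset("x", (g(0, 5), g(2, 6)))


class TestAnovaLsd:
    def test_fluoride_loael_is_20(self, table3):
        """On the bundled 1 dpf mortality data, 20 mg/L is the lowest dose
        significantly above control."""
        res = anova_lsd(table3["cm_1dpf"])
        assert res.loael == 20.0
        assert res.noael == 10.0

    def test_majority_call_across_endpoints(self, table3):
        results = [anova_lsd(ds) for ds in table3.values()]
        assert loael_majority(results) == 20.0

    def test_two_group_lsd_matches_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(10, 3, 6), rng.normal(16, 3, 6)
        ds = summarize_groups({0.0: a, 1.0: b, 2.0: b + 1})
        res = anova_lsd(ds)
        # with >2 groups the LSD uses pooled MSE; rebuild the same t manually
        n, m, s = ds.n_reps.astype(float), ds.means, ds.sds
        mse = np.sum((n - 1) * s**2) / (n.sum() - 3)
        t = (m[1] - m[0]) / np.sqrt(mse * (1 / n[0] + 1 / n[1]))
        p = 2 * stats.t.sf(abs(t), int(n.sum() - 3))
        assert res.p_values[0] == pytest.approx(p, rel=1e-12)

    def test_sufficient_statistics_equal_raw_anova(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            raw = {d: rng.normal(10 + 3 * d, 2, 5) for d in (0.0, 1.0, 2.0, 4.0)}
            ds = summarize_groups(raw)
            res = anova_lsd(ds)
            f_ref, p_ref = stats.f_oneway(*raw.values())
            assert res.anova_f == pytest.approx(f_ref, rel=1e-9)
            assert res.anova_p == pytest.approx(p_ref, rel=1e-9)

    def test_response_scaling_leaves_p_values_unchanged(self):
        rng = np.random.default_rng(5)
        raw = {d: rng.normal(5 + d, 1.5, 4) for d in (0.0, 1.0, 3.0)}
        p1 = anova_lsd(summarize_groups(raw)).p_values
        p2 = anova_lsd(summarize_groups({d: 7 * v for d, v in raw.items()})).p_values
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_identical_groups_give_no_flags(self):
        g = lambda d: DoseGroupSummary(d, 6, 10.0, 2.0)
        ds = DoseResponseDataset("x", tuple(g(d) for d in (0.0, 1.0, 2.0, 4.0)))
        res = anova_lsd(ds)
        assert not any(res.significant)
        assert res.loael is None and res.noael == 4.0

    def test_constant_data_warns_and_unflags(self):
        g = lambda d: DoseGroupSummary(d, 6, 10.0, 0.0)
        ds = DoseResponseDataset("x", tuple(g(d) for d in (0.0, 1.0, 2.0)))
        with pytest.warns(UserWarning, match="MSE"):
            res = anova_lsd(ds)
        assert not any(res.significant)


class TestCsvInput:
    def test_summary_round_trip(self, table3, tmp_path):
        path = tmp_path / "t.csv"
        table3["cm_1dpf"].to_frame().to_csv(path, index=False)
        again = read_summary_csv(path)["cm_1dpf"]
        assert np.allclose(again.means, table3["cm_1dpf"].means)
        assert np.allclose(again.sds, table3["cm_1dpf"].sds)

    def test_replicate_format(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "endpoint,dose_mg_L,replicate,response_pct\n"
            + "\n".join(
                f"cm,{d},{r},{v}"
                for d, vals in {0: [1, 3], 10: [10, 14], 20: [30, 34]}.items()
                for r, v in enumerate(vals)
            )
        )
        ds = read_replicate_csv(path)["cm"]
        assert ds.means == pytest.approx([2.0, 12.0, 32.0])

    def test_bundled_table_shape(self, table3):
        assert set(table3) == {
            "cm_1dpf", "cm_2dpf", "cm_3dpf", "cm_4dpf", "cm_5dpf", "cma_5dpf"
        }
        for ds in table3.values():
            assert len(ds.groups) == 14
            assert ds.max_dose == 300.0
            assert np.all(ds.n_reps == 6)
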