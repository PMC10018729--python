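from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from meltrisk.errors import InsufficientData, UndefinedRemoval, ValidationError
from meltrisk.synth import WwtpScenario, generate_compound_library, generate_wwtp_series
from meltrisk.wwtp import (
    RemovalBin,
    SourceClass,
    Stream,
    WwtpSeries,
    attribute_sources,
    classify_source,
    cumulative_load,
    removal_analysis,
    removal_rate,
    spearman_flow_correlation,
)
from tests.conftest import spearman_oracle


def make_series(conc, flow=None, stream=Stream.INFLUENT, censored=None, cid="c1"):
    n = len(conc)
    flow = flow if flow is not None else [1000.0 * (i + 1) for i in range(n)]
    df = pd.DataFrame(
        {
            "date": [date(2021, 2, 17) + timedelta(days=i) for i in range(n)],
            "flow_m3_per_day": flow,
            "compound_id": cid,
            "concentration_ng_L": conc,
            "censored": censored if censored is not None else [False] * n,
        }
    )
    return WwtpSeries(df, stream)


class TestSpearman:
    def test_perfect_monotone_increase(self):
        series = make_series([1.0, 2.0, 5.0, 9.0, 20.0, 30.0])
        rho, n = spearman_flow_correlation(series, "c1")
        assert rho == 1.0 and n == 6

    def test_perfect_monotone_decrease(self):
        series = make_series([30.0, 20.0, 9.0, 5.0, 2.0, 1.0])
        rho, _ = spearman_flow_correlation(series, "c1")
        assert rho == -1.0

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            conc = rng.uniform(0, 100, size=n)
            flow = rng.uniform(500, 5000, size=n)
            series = make_series(list(conc), list(flow))
            rho, _ = spearman_flow_correlation(series, "c1")
            assert rho == pytest.approx(spearman_oracle(conc, flow), abs=1e-12)

    def test_censored_days_excluded_and_insufficient_pairs_signalled(self):
        series = make_series([1.0, 2.0, 3.0, 4.0], censored=[False, True, True, False])
        with pytest.raises(InsufficientData):
            spearman_flow_correlation(series, "c1")

    def test_constant_concentration_has_no_association(self):
        series = make_series([5.0, 5.0, 5.0, 5.0])
        rho, _ = spearman_flow_correlation(series, "c1")
        assert rho == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        conc = rng.uniform(1, 100, size=6)
        flow = rng.uniform(500, 5000, size=6)
        rho1, _ = spearman_flow_correlation(make_series(list(conc), list(flow)), "c1")
        rho2, _ = spearman_flow_correlation(
            make_series(list(np.exp(conc / 20)), list(flow)), "c1"
        )
        assert rho1 == pytest.approx(rho2, abs=1e-15)


class TestClassifySource:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (0.8, SourceClass.RUNOFF_DOMINATED),
            (-0.7, SourceClass.DILUTED_OTHER_SOURCE),
            (0.5, SourceClass.MIXED),
            (-0.5, SourceClass.MIXED),
            (0.0, SourceClass.MIXED),
        ],
    )
    def test_cutoff_convention(self, rho, expected):
        assert classify_source(rho) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_source(1.5)


class TestLoadsAndRemoval:
    def test_all_censored_gives_zero_load_and_flag(self):
        series = make_series([1.0, 1.0, 1.0], censored=[True] * 3)
        load, all_censored = cumulative_load(series, "c1")
        assert load == 0.0 and all_censored

    def test_constant_closed_form(self):
        series = make_series([100.0] * 4, flow=[2000.0, 3000.0, 2500.0, 1500.0])
        load, _ = cumulative_load(series, "c1")
        assert load == pytest.approx(100.0 * 9000.0 * 1e-3)

    def test_random_series_match_summation_oracle(self):
        rng = np.random.default_rng(5)
        conc = rng.uniform(0, 500, size=6)
        flow = rng.uniform(1000, 9000, size=6)
        cens = rng.random(6) < 0.3
        series = make_series(list(conc), list(flow), censored=list(cens))
        load, _ = cumulative_load(series, "c1")
        expected = sum(c * f for c, f, z in zip(conc, flow, cens) if not z) * 1e-3
        assert load == pytest.approx(expected, rel=1e-12)

    def test_worked_example_99_percent(self):
        res = removal_rate(100.0, 1.0)
        assert res.removal_rate == pytest.approx(0.99)
        assert res.bin is RemovalBin.HIGH

    @pytest.mark.parametrize(
        "inf,eff,expected_rate,expected_bin",
        [
            (100.0, 100.0, 0.0, RemovalBin.LOW),
            (100.0, 120.0, -0.2, RemovalBin.NEGATIVE),
            (100.0, 20.0, 0.8, RemovalBin.MEDIUM),   # 80% exactly is medium
            (100.0, 50.0, 0.5, RemovalBin.MEDIUM),   # 50% exactly is medium
            (100.0, 30.0, 0.7, RemovalBin.MEDIUM),
        ],
    )
    def test_bin_boundaries(self, inf, eff, expected_rate, expected_bin):
        res = removal_rate(inf, eff)
        assert res.removal_rate == pytest.approx(expected_rate)
        assert res.bin is expected_bin

    def test_effluent_below_mdl_bin(self):
        res = removal_rate(100.0, 0.0, effluent_all_censored=True)
        assert res.bin is RemovalBin.EFFLUENT_BELOW_MDL
        assert res.removal_rate == 1.0

    def test_zero_influent_load_undefined(self):
        with pytest.raises(UndefinedRemoval):
            removal_rate(0.0, 1.0)

    def test_scale_invariance(self):
        r1 = removal_rate(100.0, 37.0).removal_rate
        r2 = removal_rate(100.0 * 7.3, 37.0 * 7.3).removal_rate
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestRemovalAnalysis:
    def test_intersection_and_window_truncation(self):
        inf = make_series([10.0] * 4, flow=[1000.0] * 4)
        eff_df = make_series([1.0] * 3, flow=[1000.0] * 3, stream=Stream.EFFLUENT)
        results, report = removal_analysis(inf, eff_df, snow_compounds={"c1", "zz"})
        assert report["n_intersection"] == 1
        assert report["window"] == (date(2021, 2, 17), date(2021, 2, 19))
        assert results[0].removal_rate == pytest.approx(0.9)

    def test_non_overlapping_windows_rejected(self):
        inf = make_series([10.0] * 3)
        eff = make_series([1.0] * 3, stream=Stream.EFFLUENT)
        eff_shifted = eff.data.copy()
        eff_shifted["date"] = [date(2022, 1, 1 + i) for i in range(3)]
        with pytest.raises(ValidationError):
            removal_analysis(inf, WwtpSeries(eff_shifted, Stream.EFFLUENT))


class TestRecoveryFromGenerator:
    def test_planted_classes_recovered_at_low_noise(self):
        library, _ = generate_compound_library(80, seed=1)
        exact = 0
        seeds = range(15)
        for seed in seeds:
            scenario = WwtpScenario.from_counts(
                library, n_runoff=13, n_diluted=27, n_mixed=23, seed=seed
            )
            series, truth = generate_wwtp_series(scenario, library)
            atts = attribute_sources(series[Stream.INFLUENT])
            got = {a.compound_id: a.source_class.value for a in atts}
            if got == truth["source_class"]:
                exact += 1
        assert exact >= 0.95 * len(seeds)

    def test_zero_noise_round_trips_exact(self):
        library, _ = generate_compound_library(60, seed=4)
        scenario = WwtpScenario.from_counts(
            library, n_runoff=5, n_diluted=5, n_mixed=4, seed=4, noise_fraction=0.0
        )
        series, truth = generate_wwtp_series(scenario, library)
        for cid in scenario.runoff_ids:
            rho, _ = spearman_flow_correlation(series[Stream.INFLUENT], cid)
            assert rho == 1.0
        for cid in scenario.diluted_ids:
            rho, _ = spearman_flow_correlation(series[Stream.INFLUENT], cid)
            assert rho == -1.0
        results, _ = removal_analysis(series[Stream.INFLUENT], series[Stream.EFFLUENT])
        rates = {r.compound_id: r for r in results}
        palette = set(truth["removal_rate"].values())
        assert any(r < 0 for r in palette) and 1.0 in palette
        for cid, true_rate in truth["removal_rate"].items():
            if true_rate >= 1.0:
                assert rates[cid].bin is RemovalBin.EFFLUENT_BELOW_MDL
            else:
                assert rates[cid].removal_rate == pytest.approx(true_rate, abs=1e-12)
                if true_rate < 0:
                    assert rates[cid].bin is RemovalBin.NEGATIVE
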