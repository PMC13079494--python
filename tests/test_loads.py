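import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasquant.loads import (
    aggregate_analyte,
    aggregate_campaign,
    censor_for_aggregation,
    daily_load,
    detection_frequency,
    pndl,
)
from pfasquant.model import Censor, ConcentrationValue, SchemaError, SiteDay
from pfasquant.registry import packaged_influent_days, packaged_site_days, packaged_wbe_summary


def cv(value=None, censor=Censor.DETECTED):
    if value is None and censor is Censor.DETECTED:
        censor = Censor.BELOW_LOD
    return ConcentrationValue(censor=censor, value=value)


class TestCensorSubstitution:
    def test_detected_passes_through(self):
        assert censor_for_aggregation(cv(176.2)) == 176.2

    def test_below_loq_contributes_zero(self):
        assert censor_for_aggregation(cv(censor=Censor.BELOW_LOQ)) == 0.0

    def test_below_lod_contributes_zero(self):
        assert censor_for_aggregation(cv(censor=Censor.BELOW_LOD)) == 0.0


class TestDetectionFrequency:
    def test_detected_days_counted(self):
        days = [cv(31.5), cv(censor=Censor.BELOW_LOD), cv(12.4)]
        assert detection_frequency(days) == 2

    def test_below_loq_counts_as_detection(self):
        days = [cv(censor=Censor.BELOW_LOQ), cv(censor=Censor.BELOW_LOD), cv(censor=Censor.BELOW_LOD)]
        assert detection_frequency(days) == 1

    def test_all_censored_is_zero(self):
        assert detection_frequency([cv(censor=Censor.BELOW_LOD)] * 3) == 0


class TestDailyLoadAndPndl:
    def test_daily_load_unit_bridge(self):
        assert daily_load(50.0, 1e8) == pytest.approx(5000.0)

    def test_zero_concentration(self):
        assert daily_load(0.0, 1e8) == 0.0

    def test_flow_consistent_with_published_load(self):
        # 60.4 ng/L at 2.289e8 L/day is the published PFNA-scale daily load
        assert daily_load(60.4, 2.289e8) == pytest.approx(13825.56, abs=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            daily_load(-1.0, 1e8)

    def test_pndl_arithmetic(self):
        assert pndl(5000.0, 1_000_000) == pytest.approx(5000.0)

    def test_pndl_normalisation_identity(self):
        # for a catchment of exactly 1000 inhabitants PNDL equals DL in µg/day
        assert pndl(3.5, 1000) == pytest.approx(3.5e3)

    def test_pndl_zero_load(self):
        assert pndl(0.0, 1234) == 0.0

    def test_pndl_requires_population(self):
        with pytest.raises(ValueError):
            pndl(1.0, 0)


class TestAggregation:
    def make_site_days(self, n=3, flow=2.289e8, population=900_000):
        return [SiteDay(day_id=i + 1, flow=flow, population=population) for i in range(n)]

    def test_cumulative_concentration_short_chain_acid(self):
        per_day = [cv(3.6), cv(2.4), cv(2.5)]
        res = aggregate_analyte("PFOA", per_day, self.make_site_days())
        assert res.cumulative_conc == pytest.approx(8.5)
        assert res.detection_frequency == 3

    def test_cumulative_concentration_with_censored_day(self):
        per_day = [cv(176.2), cv(21.9), cv(censor=Censor.BELOW_LOQ)]
        res = aggregate_analyte("8:2 diPAP", per_day, self.make_site_days())
        assert res.cumulative_conc == pytest.approx(198.1)
        assert res.detection_frequency == 3
        assert res.cumulative_conc_sd == pytest.approx(109.1, abs=0.05)

    def test_all_censored_gives_zeros(self):
        per_day = [cv(censor=Censor.BELOW_LOD)] * 3
        res = aggregate_analyte("X", per_day, self.make_site_days())
        assert res.cumulative_conc == 0.0
        assert res.cumulative_dl == 0.0
        assert res.cumulative_pndl == 0.0
        assert res.detection_frequency == 0
        assert res.cumulative_conc_sd is None

    def test_day_alignment_enforced(self):
        with pytest.raises(SchemaError):
            aggregate_analyte("X", [cv(1.0)], self.make_site_days(3))

    def test_missing_flow_for_detected_day_errors(self):
        conc = pd.DataFrame(
            {"analyte": ["X"], "day": [9], "censor": [Censor.DETECTED], "value": [5.0]}
        )
        with pytest.raises(SchemaError, match="day 9"):
            aggregate_campaign(conc, self.make_site_days(3))

    @settings(deadline=None, max_examples=60)
    @given(
        concs=st.lists(st.floats(0.0, 1e4), min_size=1, max_size=6),
        flow=st.floats(1e6, 1e9),
        population=st.integers(1000, 2_000_000),
    )
    def test_additivity_over_day_partition(self, concs, flow, population):
        days = [SiteDay(day_id=i + 1, flow=flow, population=population) for i in range(len(concs))]
        values = [cv(c) for c in concs]
        full = aggregate_analyte("X", values, days)
        k = len(concs) // 2
        left = aggregate_analyte("X", values[:k], days[:k]) if k else None
        right = aggregate_analyte("X", values[k:], days[k:])
        total_dl = (left.cumulative_dl if left else 0.0) + right.cumulative_dl
        total_conc = (left.cumulative_conc if left else 0.0) + right.cumulative_conc
        assert full.cumulative_dl == pytest.approx(total_dl, rel=1e-9)
        assert full.cumulative_conc == pytest.approx(total_conc, rel=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(
        concs=st.lists(st.floats(0.0, 1e4), min_size=1, max_size=6),
        flow=st.floats(1e6, 1e9),
        population=st.integers(1000, 2_000_000),
    )
    def test_doubling_flow_doubles_loads_not_concentrations(self, concs, flow, population):
        days = [SiteDay(day_id=i + 1, flow=flow, population=population) for i in range(len(concs))]
        days2 = [SiteDay(day_id=d.day_id, flow=2 * d.flow, population=d.population) for d in days]
        values = [cv(c) for c in concs]
        base = aggregate_analyte("X", values, days)
        doubled = aggregate_analyte("X", values, days2)
        assert doubled.cumulative_dl == pytest.approx(2 * base.cumulative_dl, rel=1e-9)
        assert doubled.cumulative_pndl == pytest.approx(2 * base.cumulative_pndl, rel=1e-9)
        assert doubled.cumulative_conc == base.cumulative_conc


class TestPublishedCampaignRegression:
    def test_cumulative_concentrations_and_frequencies(self):
        results = {
            r.analyte_name: r
            for r in aggregate_campaign(packaged_influent_days(), packaged_site_days())
        }
        summary = packaged_wbe_summary()
        for row in summary.itertuples():
            res = results[row.analyte]
            assert res.detection_frequency == row.detection_frequency, row.analyte
            if not row.conc_consistent:
                continue  # one published row is internally inconsistent
            # per-day inputs are printed to 0.1 ng/L; summing three gives 0.15
            assert res.cumulative_conc == pytest.approx(row.cumulative_conc, abs=0.15), row.analyte
            if not np.isnan(row.cumulative_conc_sd) and res.cumulative_conc_sd is not None:
                assert res.cumulative_conc_sd == pytest.approx(
                    row.cumulative_conc_sd, abs=0.15
                ), row.analyte

    def test_undetected_analytes_all_zero(self):
        results = aggregate_campaign(packaged_influent_days(), packaged_site_days())
        detected = set(packaged_wbe_summary()["analyte"])
        for r in results:
            if r.analyte_name not in detected:
                assert r.detection_frequency == 0
                assert r.cumulative_conc == 0.0
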