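import dataclasses

import pytest

from pfasquant.model import AnalyteClass, AnalyteSpec, QuantStatus, SiteDay, TransitionSpec
from pfasquant.registry import packaged_analyte_registry
from pfasquant.simulate import AnalyteTruth, AssayTruth, CampaignDesign, IstdTruth


def make_analyte(
    name="PFX",
    istd="ISTD-1",
    calib_low=0.01,
    calib_high=1000.0,
    two_transitions=True,
    status=QuantStatus.QUANTITATIVE,
    analyte_class=AnalyteClass.PFSA,
):
    quant = TransitionSpec(400.0, 99.0, 40.0, 30.0)
    qual = TransitionSpec(400.0, 80.0, 40.0, 30.0) if two_transitions else None
    return AnalyteSpec(
        name=name,
        analyte_class=analyte_class,
        quant_transition=quant,
        qual_transition=qual,
        istd_name=istd,
        calib_low=calib_low,
        calib_high=calib_high,
        status=status,
    )


@pytest.fixture(scope="session")
def registry():
    return packaged_analyte_registry()


@pytest.fixture
def simple_analyte():
    return make_analyte()


@pytest.fixture
def site_days():
    return [
        SiteDay(day_id=1, flow=2.289e8, population=900_000),
        SiteDay(day_id=2, flow=2.289e8, population=900_000),
        SiteDay(day_id=3, flow=2.289e8, population=900_000),
    ]


def make_truth(
    names=("PFX",),
    response_factor=0.05,
    noise_cv=0.05,
    istd_cv=0.05,
    true_recovery=1.0,
    ion_ratio=2.0,
    sn_per_conc=1000.0,
    **kwargs,
):
    analytes = {
        n: AnalyteTruth(
            response_factor=response_factor,
            true_recovery=true_recovery,
            ion_ratio_true=ion_ratio,
            noise_cv=noise_cv,
            sn_per_conc=sn_per_conc,
            **kwargs,
        )
        for n in names
    }
    return AssayTruth(analytes=analytes, istds={"ISTD-1": IstdTruth(istd_cv=istd_cv)})


@pytest.fixture
def simple_truth():
    return make_truth()


@pytest.fixture
def small_design(site_days):
    return CampaignDesign(
        calib_levels=(0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
        n_injection_replicates=3,
        qc_levels=(5.0, 20.0, 200.0, 500.0),
        spike_levels=(5.0, 20.0, 200.0, 500.0),
        n_matrix_replicates=3,
        influent_days=site_days,
        seed=17,
    )
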