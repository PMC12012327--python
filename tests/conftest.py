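import pytest

from opcycle import PhaseDurations, PopulationSpec


@pytest.fixture
def control_phases() -> PhaseDurations:
    """Phase durations matching a fast-cycling control population
    (T_C = 76.6 h, T_S = 13.5 h, T_G2 = 1.8 h, M neglected)."""
    return PhaseDurations(t_g1=61.3, t_s=13.5, t_g2=1.8, t_m=0.0)


@pytest.fixture
def cko_phases() -> PhaseDurations:
    """Slow-cycling knockout-like population (T_C = 179 h, T_S = 16.7 h)."""
    return PhaseDurations(t_g1=159.3, t_s=16.7, t_g2=3.0, t_m=0.0)


@pytest.fixture
def control_spec(control_phases) -> PopulationSpec:
    return PopulationSpec.single(control_phases, growth_fraction=1.0)


def noise_free_points(phases, g, times):
    """Exact expected labeling-curve points (fractional counts)."""
    from opcycle import LabelingCurvePoint, expected_li

    return [
        LabelingCurvePoint(t=t, n_total=1.0, n_labeled=expected_li(phases, g, t))
        for t in times
    ]
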