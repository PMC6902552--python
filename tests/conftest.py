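import numpy as np
import pytest

from infradian.activity import ActivityTrace, summarize_traces
from infradian.metabolome import normalize_to_internal_standard
from infradian.predictor import PredictorConfig
from infradian.simulate import SimConfig, simulate_cohort

#: small grid used for Monte-Carlo work throughout the suite
MC_CONFIG = PredictorConfig(k_grid=(1, 2, 3, 4, 5))


def make_trace(
    mouse_id="m1",
    days=5,
    bin_hours=1.0,
    rate_cm_per_h=100.0,
    distances=None,
    sampling_day=None,
):
    """A trace covering `days` full days, sampled at ZT6 of the last day."""
    n_bins = int(round(days * 24 / bin_hours))
    starts = np.arange(n_bins) * bin_hours
    if distances is None:
        distances = np.full(n_bins, rate_cm_per_h * bin_hours)
    sampling_day = days - 1 if sampling_day is None else sampling_day
    return ActivityTrace(
        mouse_id=mouse_id,
        bin_starts=starts,
        distances=np.asarray(distances, float),
        bin_hours=bin_hours,
        sampling_time=24.0 * sampling_day + 6.0,
    )


SMALL_SIM = SimConfig(
    n_mice=12, n_metabolites=10, n_coupled=2, trace_days=40, seed=42
)


@pytest.fixture(scope="session")
def small_cohort():
    """12 mice x 10 metabolites, 2 coupled — cheap end-to-end fixture."""
    traces, met, expr, truth = simulate_cohort(SMALL_SIM)
    matrix = normalize_to_internal_standard(met)
    summaries = summarize_traces(traces)
    return traces, matrix, expr, truth, summaries


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort: 35 mice x 106 metabolites, 10 coupled at R^2=0.5."""
    traces, met, expr, truth = simulate_cohort(SimConfig(seed=7))
    matrix = normalize_to_internal_standard(met)
    summaries = summarize_traces(traces)
    return traces, matrix, expr, truth, summaries
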