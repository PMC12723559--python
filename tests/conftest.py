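import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trace(values, fs=2000.0):
    """Minimal trace object (values in μV, fs in Hz) for spectral tests."""

    class _Trace:
        def __init__(self, values, fs):
            self.values = np.asarray(values, dtype=float)
            self.fs = fs

    return _Trace(values, fs)


def pink_noise(rng, n, fs):
    """Unit-SD 1/f-amplitude noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n)
    return x / x.std()


@pytest.fixture(scope="session")
def five_condition_report():
    """Scaled five-condition experiment: 400-neuron circuits, 5 randomized
    circuits per condition, 8 s resting runs and 20 trials per protocol.

    Session-scoped because the simulations dominate suite runtime; every
    downstream test reads from the same report.
    """
    from agecircuit.microcircuit import CircuitConfig
    from agecircuit.pipeline import ExperimentConfig, run_experiment

    cfg = ExperimentConfig(
        circuit=CircuitConfig(n_total=400),
        n_circuits=5,
        baseline_duration_ms=8000.0,
        decoder_n_perm=25,
        detect_oscillation_events=False,
    )
    return run_experiment(cfg, seed=7, on_error="raise")


@pytest.fixture(scope="session")
def condition_medians(five_condition_report):
    return five_condition_report.results.groupby("condition").median(numeric_only=True)
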