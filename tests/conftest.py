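import pytest

from shockagree.pipeline import analyze_bundle
from shockagree.synthetic import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 250-patient bundle with defaults: exercises every exclusion path."""
    cfg = SimulationConfig(n_patients=250, seed=42)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    bundle, truth = small_bundle
    return analyze_bundle(bundle, run_stats=False), truth
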