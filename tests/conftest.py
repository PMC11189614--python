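import pytest

from riboflux import SimDesign, simulate_counts, fit_interaction


@pytest.fixture(scope="session")
def default_experiment():
    """The default simulated study (seed 1): 200 genes, 2 RPF + 3 RNA reps."""
    return simulate_counts(SimDesign(seed=1))


@pytest.fixture(scope="session")
def default_fits(default_experiment):
    """Interaction fits for both assays on the default experiment."""
    exp = default_experiment
    return {
        "RPF": fit_interaction(exp.counts, exp.sheet, "RPF"),
        "RNA": fit_interaction(exp.counts, exp.sheet, "RNA"),
    }
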