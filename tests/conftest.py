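import numpy as np
import pytest
from hypothesis import settings

import msatpipe as mp

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return mp.builtin_panel()


@pytest.fixture()
def clean_conditions():
    """Noise-free instrument model: render/measure errors only."""
    return mp.RunConditions(
        migration_sd=0.0, bleed=0.0, spike_rate=0.0, nonspecific_rate=0.0,
        baseline_level=0.0, noise_sd=0.0,
    )


@pytest.fixture()
def nominal_conditions():
    """Default study conditions (migration noise, bleed, spikes, baseline)."""
    return mp.RunConditions()


def genotype_and_compare(panel, genotypes, conditions, rng, groups=(1, 2)):
    """Run the full pipeline on simulated samples; return (observed, expected)."""
    observed, expected = {}, {}
    for g in genotypes:
        traces = {
            grp: mp.simulate_run(g, panel, grp, run=conditions, rng=rng)[0]
            for grp in groups
        }
        observed[g.subject] = mp.genotype_sample(traces, panel, run_id=g.subject)
        expected[g.subject] = g.expected_bins()
    return observed, expected
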