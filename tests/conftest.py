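import numpy as np
import pandas as pd
import pytest

from qkisplice.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_clip_profiles,
    generate_cohort,
    generate_emt_experiment,
    make_event_table,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort: 120 samples, 40 events, 10 responsive."""
    cfg = SimulationConfig(
        n_samples=120, n_events=40, n_responsive_events=10,
        mean_junction_coverage=100, seed=101,
    )
    expression, mirna, junctions, events, truth = generate_cohort(cfg)
    return cfg, expression, mirna, junctions, events, truth


@pytest.fixture(scope="session")
def emt_experiment():
    cfg = SimulationConfig(
        n_samples=10, n_events=40, n_responsive_events=10,
        mean_junction_coverage=100, target_delta_psi=0.5, seed=202,
    )
    counts, events, truth = generate_emt_experiment(cfg)
    return cfg, counts, events, truth


@pytest.fixture(scope="session")
def clip_setup():
    events = make_event_table(60)
    truth = GroundTruth()
    for i, ev in enumerate(events.event_id):
        truth.true_delta_psi[ev] = 0.0
        if i < 10:
            truth.responsive_event_ids.add(ev)
            truth.true_delta_psi[ev] = -0.4
            truth.true_binding_side[ev] = "upstream_intron"
        elif i < 20:
            truth.responsive_event_ids.add(ev)
            truth.true_delta_psi[ev] = 0.4
            truth.true_binding_side[ev] = "downstream_intron"
        else:
            truth.true_binding_side[ev] = "none"
    peaks = generate_clip_profiles(events, truth, seed=303)
    return events, truth, peaks
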