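import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rnaiscreen.simulate import (
    ACTIVE,
    CONTROL,
    TREATED,
    UNTREATED,
    ScenarioConfig,
    ScreenDataset,
    ScreenDesign,
    simulate_screen,
)

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


def make_toy_screen(active, controls, plate=1):
    """Build a one-plate ScreenDataset from explicit well values.

    ``active`` maps sirna_id -> (untreated values, treated values);
    ``controls`` is (untreated values, treated values) for the NS wells.
    """
    rows = []
    for sid, (unt, trt) in active.items():
        for cond, vals in ((UNTREATED, unt), (TREATED, trt)):
            for i, v in enumerate(vals, start=1):
                rows.append((plate, i, cond, ACTIVE, sid, float(v)))
    for cond, vals in ((UNTREATED, controls[0]), (TREATED, controls[1])):
        for i, v in enumerate(vals, start=1):
            rows.append((plate, i, cond, CONTROL, "", float(v)))
    wells = pd.DataFrame(
        rows, columns=["plate", "replicate", "condition", "kind", "sirna_id", "viability"]
    )
    return ScreenDataset(wells=wells)


@pytest.fixture(scope="session")
def default_screen():
    """One simulated screen under scenario defaults (seeded)."""
    cfg = ScenarioConfig(seed=1234)
    return simulate_screen(cfg, ScreenDesign(replicates_per_condition=3))


@pytest.fixture(scope="session")
def small_screen():
    """A small, fast screen: 2 plates x 10 siRNAs, r=3, moderate noise."""
    cfg = ScenarioConfig(sigma=0.4, n_hit_low=2, n_hit_high=4, seed=99)
    design = ScreenDesign(
        n_plates=2, wells_per_plate=12, sirna_wells_per_plate=10,
        control_wells_per_plate=2, replicates_per_condition=3,
    )
    return simulate_screen(cfg, design)
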