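import pandas as pd
import pytest

from hiddenpop import CaptureHistogram, EpochCounts, EventTable, SimulationConfig, simulate_registry

# Printed worked-example inputs: the raster-figure epoch counts and the
# opiate-overdose care histogram (262 persons ever in care, 75 once, 55
# twice; true census 486 deceased, 485 with linkable records).
FIG1_COUNTS = (19, 10, 8)
OVERDOSE_OBSERVED = 262
OVERDOSE_H1 = 75
OVERDOSE_H2 = 55
OVERDOSE_CENSUS = 485


@pytest.fixture
def fig1_counts():
    return EpochCounts(FIG1_COUNTS, d=20)


@pytest.fixture
def overdose_hist():
    return CaptureHistogram(
        {1: OVERDOSE_H1, 2: OVERDOSE_H2}, observed_total=OVERDOSE_OBSERVED
    )


@pytest.fixture
def small_registry():
    """Homogeneous simulated register at the raster-figure scale."""
    return simulate_registry(SimulationConfig(N=50, T=60, p1=0.025, seed=11))


@pytest.fixture
def toy_events():
    """Hand-built table: a seen once, b and c seen twice each."""
    df = pd.DataFrame(
        {
            "person_id": ["a", "b", "b", "c", "c"],
            "time": [1, 0, 30, 5, 6],
        }
    )
    return EventTable(events=df, T=60)
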