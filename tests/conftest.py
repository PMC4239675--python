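from pathlib import Path

import numpy as np
import pytest

from openadj.copymap import assign_delta, build_boundary_intervals
from openadj.counterparts import match_counterparts
from openadj.signatures import classify_adjacencies
from openadj.simulator import observe, simulate_history

DATA_DIR = Path(__file__).parent / "data"

# Exact-mode simulation settings: cut spacing comfortably above both the
# counterpart threshold (2 kb) and the boundary-interval half-width (5 kb),
# and cuts kept away from chromosome ends, so matching and delta assignment
# are free of resolution artifacts.
EXACT = dict(min_spacing=6000, edge_margin=60_000)
REFERENCE = {"chr1": 80_000_000, "chr2": 80_000_000}


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


def simulate_exact(ks, seed, reference=None, circle_loss_p=1.0, set_id="sim"):
    """One exact (no dropout/jitter) simulated observation."""
    rng = np.random.default_rng(seed)
    genome, history = simulate_history(
        reference or REFERENCE, ks, circle_loss_p=circle_loss_p, rng=rng, **EXACT
    )
    obs = observe(genome, history, rng=rng, set_id=set_id)
    return genome, history, obs


def classify_exact(obs, D=2000, L=10_000):
    """Run the standard classification pipeline on a simulated observation."""
    pairing = match_counterparts(obs.adjset, D)
    delta = assign_delta(obs.adjset, build_boundary_intervals(obs.segments, L))
    calls = classify_adjacencies(obs.adjset, pairing, delta)
    return calls, pairing, delta
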