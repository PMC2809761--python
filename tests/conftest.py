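from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from intronevol.simulate import SimulationParams, simulate_turnover


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic dataset (all event types on)."""
    return simulate_turnover(SimulationParams(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def clean_sim():
    """Synthetic dataset without coding-change variants or planted repeats,
    so intron sites must be recovered 1:1 against truth at slack=0."""
    return simulate_turnover(
        SimulationParams(
            n_genes=80, seed=5, p_coding_change=0.0, p_planted_repeat=0.0
        )
    )


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory, small_sim):
    """Full pipeline run on the small dataset."""
    from intronevol import pipeline
    from intronevol.simulate import write_dataset

    out = tmp_path_factory.mktemp("run")
    (out / "data").mkdir()
    write_dataset(small_sim, out / "data")
    pipeline.stage_all(out, {"splice": {"B": 500, "seed": 3}})
    return out
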