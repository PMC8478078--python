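import numpy as np
import pandas as pd
import pytest

import synergy_screen as ss
from synergy_screen import Trait


@pytest.fixture(scope="session")
def default_screen() -> ss.SimulatedScreen:
    """One full 13-isolate screen under the default effect model."""
    return ss.simulate_screen(ss.SimulationConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_sg(default_screen) -> pd.DataFrame:
    return ss.standardize_dataset(default_screen.plants)


@pytest.fixture
def make_sg_frame():
    """Build a standardized-record frame from (treatment spec, trait, sg) rows.

    Each row is ``(kind, isolates, round_id, trait, sg)`` with isolates a
    tuple; plant ids are synthesized.
    """

    def _make(rows) -> pd.DataFrame:
        out = []
        for i, (kind, isolates, round_id, trait, sg) in enumerate(rows):
            isolates = tuple(sorted(isolates))
            out.append(
                {
                    "plant_id": f"p{i:04d}",
                    "treatment": "control" if kind == "control" else "+".join(isolates),
                    "treatment_kind": kind,
                    "isolate_a": isolates[0] if isolates else "",
                    "isolate_b": isolates[1] if len(isolates) == 2 else "",
                    "round_id": round_id,
                    "trait": Trait(trait).value,
                    "sg": float(sg),
                }
            )
        return pd.DataFrame(out)

    return _make


@pytest.fixture
def make_plant_frame():
    """Build a raw plant-record frame from
    ``(plant_id, kind, isolates, round_id, sdw, leaves, spad)`` rows."""

    def _make(rows) -> pd.DataFrame:
        out = []
        for plant_id, kind, isolates, round_id, sdw, leaves, spad in rows:
            isolates = tuple(sorted(isolates))
            out.append(
                {
                    "plant_id": plant_id,
                    "treatment_kind": kind,
                    "isolate_a": isolates[0] if isolates else "",
                    "isolate_b": isolates[1] if len(isolates) == 2 else "",
                    "round_id": round_id,
                    "shoot_dry_weight": sdw,
                    "n_mature_leaves": leaves,
                    "spad": spad,
                }
            )
        return pd.DataFrame(out)

    return _make
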