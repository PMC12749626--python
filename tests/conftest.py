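import numpy as np
import pytest

from reactionfunnel.surf import ReactionDataset, ReactionRecord


def make_record(i: int = 0, **overrides) -> ReactionRecord:
    base = dict(
        reaction_id=f"R{i:04d}",
        arene="c1ccncc1",
        acid="CC(C)(C)C(=O)O",
        catalyst="AgNO3",
        additive="TFA",
        reagent="(NH4)2S2O8",
        solvent="MeCN/H2O 3:2",
        atmosphere="air",
        yield_mono=0.10,
        yield_di=0.02,
    )
    base.update(overrides)
    return ReactionRecord(**base)


@pytest.fixture
def six_record_dataset() -> ReactionDataset:
    arenes = ["c1ccncc1", "c1cnc(C)nc1", "c1ccc2ncccc2c1"]
    acids = ["CC(C)(C)C(=O)O", "OC(=O)C1CCC1"]
    records = []
    i = 0
    for arene in arenes:
        for acid in acids:
            records.append(
                make_record(
                    i,
                    arene=arene,
                    acid=acid,
                    yield_mono=round(0.05 * i, 3),
                    yield_di=round(0.01 * (i % 3), 3),
                )
            )
            i += 1
    return ReactionDataset(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
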