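import numpy as np
import pytest

from lidosc import preprocess, synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    """Two structures, four wires each, 60 s, no bursts (pure background)."""
    spec = synthgen.SessionSpec(
        duration_s=60.0,
        structures=[
            synthgen.StructureSpec("M1FL", n_wires=4),
            synthgen.StructureSpec("DLS", n_wires=4),
        ],
        seed=7,
    )
    session, truth = synthgen.generate_session(spec)
    return session, truth


def make_channel_map(n_structs=2, n_wires=4):
    records = []
    wid = 0
    names = ["M1FL", "DLS", "GPe", "SNr"]
    for b in range(n_structs):
        for _ in range(n_wires):
            records.append((wid, names[b % len(names)], "lesioned", b))
            wid += 1
    return preprocess.ChannelMap.from_records(records)
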