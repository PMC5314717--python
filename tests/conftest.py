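import numpy as np
import pytest

from epiland import (
    BooleanNetwork,
    TruthTable,
    build_core_grn,
)


@pytest.fixture(scope="session")
def core():
    return build_core_grn()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toggle():
    """Two-node mutual-inhibition switch (classic toggle)."""
    return BooleanNetwork(
        nodes=("a", "b"),
        rules={
            "a": TruthTable(regulators=("b",), outputs=(1, 0)),
            "b": TruthTable(regulators=("a",), outputs=(1, 0)),
        },
    )


@pytest.fixture
def self_activator():
    return BooleanNetwork(
        nodes=("x",),
        rules={"x": TruthTable(regulators=("x",), outputs=(0, 1))},
    )
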