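import pytest

from biopetri import Marking, PetriNetStructure, build_dana

# Verbatim row-major digit strings of the DANA model's published 6x8
# input/output/incidence matrices (rows T0..T5, columns P0..P7).
DANA_A_MINUS_DIGITS = "001000101000000001000001110000000001100000100000"
DANA_A_PLUS_DIGITS = "110000000001000000001000001000000010010000000100"
DANA_A_DIGITS = (
    "11-1000-10-100100000-100100-1-1-1100000001-1-110000-100100"
)

# Published minimal S-invariants of the DANA net and its initial marking.
DANA_Y1 = (1, 0, 1, 1, 1, 1, 0, 1)
DANA_Y2 = (0, 1, 1, 0, 2, 1, 0, 1)
DANA_M0 = (0, 0, 1, 0, 0, 0, 1, 1)


def parse_digit_matrix(digits: str, n_rows: int, n_cols: int):
    """Row-major signed-digit string -> list of int rows."""
    import re

    cells = [int(tok) for tok in re.findall(r"-?\d", digits)]
    assert len(cells) == n_rows * n_cols
    return [cells[i * n_cols : (i + 1) * n_cols] for i in range(n_rows)]


@pytest.fixture(scope="session")
def dana():
    return build_dana()


@pytest.fixture(scope="session")
def dana_net(dana):
    return dana.net


@pytest.fixture(scope="session")
def dana_m0():
    return Marking(DANA_M0)


@pytest.fixture()
def cycle_net():
    """Two-place cycle: p1 -> t1 -> p2 -> t2 -> p1."""
    return PetriNetStructure(
        places=["p1", "p2"],
        transitions=["t1", "t2"],
        pre={("t1", "p1"): 1, ("t2", "p2"): 1},
        post={("t1", "p2"): 1, ("t2", "p1"): 1},
    )


@pytest.fixture()
def self_loop_net():
    """Single place/transition pair with pre = post = 1."""
    return PetriNetStructure(
        places=["p"],
        transitions=["t"],
        pre={("t", "p"): 1},
        post={("t", "p"): 1},
    )
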