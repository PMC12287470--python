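import numpy as np
import pytest

from satarray.simulate import type_consensus_unit

TYPE_NAMES = ("L47", "L49", "L50", "L53")


@pytest.fixture(scope="session")
def consensus_units() -> dict[str, str]:
    return {t: type_consensus_unit(t) for t in TYPE_NAMES}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def rm_out_file(tmp_path):
    """RepeatMasker .out fixture: 5 rows, 2 of them D20S16, one on minus strand."""
    rows = [
        "  225  1.5  0.0  0.0  chr20  101  150  (0)  +  D20S16  Satellite",
        "  200  2.0  0.0  0.0  chr20  201  260  (0)  C  D20S16  Satellite",
        "  180  3.0  0.0  0.0  chr20  161  190  (0)  +  MLT2B4  LTR/ERVL",
        "  170  3.5  0.0  0.0  chr3  501  560  (0)  +  MLT2B4  LTR/ERVL",
        "  160  4.0  0.0  0.0  chr3  11  60  (0)  +  ALR  Satellite",
    ]
    path = tmp_path / "fixture.out"
    path.write_text(
        "   SW  perc perc perc  query  position in query  matching repeat\n"
        "score  div. del. ins.  sequence  begin end (left)  repeat  class/family\n"
        "\n" + "\n".join(rows) + "\n"
    )
    return path
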