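import numpy as np
import pytest

import cycshell as cs


@pytest.fixture(scope="session")
def default_shell():
    """The full default 432-peptide shell (shared; construction is cheap)."""
    return cs.build_shell()


@pytest.fixture(scope="session")
def small_shell():
    """A sparse 8-unit shell for fast geometry tests."""
    return cs.build_shell(cs.ShellSpec(n_units=8, seed=1))


@pytest.fixture()
def water_pdb(tmp_path):
    """Smallest valid input: one 3-atom water molecule."""
    path = tmp_path / "water.pdb"
    path.write_text(
        "CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  O   HOH    1      10.000  10.000  10.000  1.00  0.00"
        "           O\n"
        "ATOM      2  H1  HOH    1      10.960  10.000  10.000  1.00  0.00"
        "           H\n"
        "ATOM      3  H2  HOH    1       9.760  10.930  10.000  1.00  0.00"
        "           H\n"
        "END\n"
    )
    return path


def rng(seed):
    return np.random.default_rng(seed)
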