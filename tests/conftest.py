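import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scdtraj.synthetic_data import get_preset, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MINIMAL_PDB = """\
ATOM      1  OE1 GLN A 147       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  HE1 TRP A 153       2.000   0.000   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


def _eight_atom_model(model_idx: int) -> str:
    lines = [f"MODEL     {model_idx + 1:4d}"]
    for i in range(8):
        x = float(i) + 0.1 * model_idx
        lines.append(
            f"ATOM  {i+1:5d}  C{i+1:<2d} LIG A 501    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
    lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


@pytest.fixture
def multimodel_pdb(tmp_path):
    """3-model PDB of the same 8 atoms."""
    p = tmp_path / "multi.pdb"
    p.write_text("".join(_eight_atom_model(m) for m in range(3)) + "END\n")
    return p


@pytest.fixture(scope="session")
def substrate_sim():
    """One moderately sized substrate trajectory shared across tests."""
    return simulate(get_preset("substrate"), 6000, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
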