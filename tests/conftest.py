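import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20140917)


def make_pdb_text(residues):
    """Hand-built PDB text from (chain, resseq, resname, [(atom, element, xyz)]).

    Kept independent of the package's own writer so parser tests do not
    round-trip through dsloop code.
    """
    lines = []
    serial = 1
    for chain, resseq, resname, atoms in residues:
        for name, element, (x, y, z) in atoms:
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {padded:4s} {resname:<3s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
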