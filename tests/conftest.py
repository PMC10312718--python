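import numpy as np
import pytest

from cryothread.labeling import Atom, Chain, Coordinate, Residue, Structure


def patch_bytes(path, offset: int, payload: bytes) -> None:
    """Overwrite raw bytes of a file in place (for crafting invalid MRCs)."""
    with open(path, "r+b") as fh:
        fh.seek(offset)
        fh.write(payload)


def make_residue(seqnum, name, ca, n=None, c=None, ss=None) -> Residue:
    residue = Residue(seqnum=seqnum, name=name, ss=ss)
    residue.atoms["CA"] = Atom("CA", Coordinate(*ca))
    if n is not None:
        residue.atoms["N"] = Atom("N", Coordinate(*n))
    if c is not None:
        residue.atoms["C"] = Atom("C", Coordinate(*c))
    return residue


def make_chain_structure(residues, chain_id="A") -> Structure:
    return Structure(chains=[Chain(chain_id=chain_id, residues=residues)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
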