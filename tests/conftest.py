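import numpy as np
import pytest

from sugarport.rin import betweenness, build_rin
from sugarport.structure import Residue, Structure
from sugarport.synthetic import ChannelSpec, make_channel_structure
from sugarport.tunnels import TunnelConfig, find_tunnels


def make_random_structure(rng, n_residues=4, atoms_per_residue=3, box=8.0):
    """Small random atom cloud grouped into single-chain residues."""
    n = n_residues * atoms_per_residue
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    names = []
    for i in range(n):
        within = i % atoms_per_residue
        names.append(["N", "CA", "CB"][within % 3])
    return Structure(
        atom_name=np.array(names),
        element=elements,
        res_seq=np.repeat(np.arange(1, n_residues + 1), atoms_per_residue),
        res_name=np.array(["ALA"] * n),
        chain=np.array(["A"] * n),
        coords=rng.uniform(0, box, size=(n, 3)),
        hetero=np.zeros(n, dtype=bool),
    )


@pytest.fixture(scope="session")
def channel():
    structure, truth = make_channel_structure(ChannelSpec(seed=11))
    return structure, truth


@pytest.fixture(scope="session")
def channel_tunnels(channel):
    structure, truth = channel
    config = TunnelConfig(start_point=truth["start_xyz"])
    return find_tunnels(structure, config)


@pytest.fixture(scope="session")
def channel_profile(channel):
    structure, _ = channel
    return betweenness(build_rin(structure))


def residue(seq, name="ALA", chain="A"):
    return Residue(chain, seq, name)
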