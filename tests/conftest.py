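import numpy as np
import pytest

from qwire.structure import AtomRecord, MacromolecularModel


def atom(
    serial,
    name,
    element,
    resname,
    chain,
    resnum,
    pos,
    hetero=False,
    subunit="unmapped",
    occupancy=1.0,
):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc="",
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        insertion_code="",
        position=np.asarray(pos, dtype=float),
        occupancy=occupancy,
        b_factor=20.0,
        is_hetero=hetero,
        subunit=subunit,
    )


def water(serial, resnum, pos, chain="W", subunit="unmapped"):
    return atom(serial, "O", "O", "HOH", chain, resnum, pos, hetero=True, subunit=subunit)


def model_of(*atoms, name="test"):
    return MacromolecularModel(list(atoms), name=name)


@pytest.fixture
def three_state_fixture():
    from qwire.synthetic import WireFixtureSpec, make_wire_fixture

    spec = WireFixtureSpec(states=("connected", "open_gap", "obstructed_gap"), seed=11)
    return make_wire_fixture(spec)


@pytest.fixture
def channel():
    from qwire.synthetic import ChannelFixtureSpec, make_channel_milestones

    return make_channel_milestones(ChannelFixtureSpec(seed=7))
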