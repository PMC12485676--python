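import numpy as np
import pytest

import cttaccess as ct


@pytest.fixture(scope="session")
def toy_dimer():
    return ct.make_toy_dimer(seed=0)


@pytest.fixture(scope="session")
def small_lattice():
    """A 4-protofilament, 2-ring lattice: fast, but exercises every
    labelling path (lateral + axial neighbours, seam closure)."""
    return ct.make_toy_lattice(n_protofilaments=4, start_number=3, n_rings=2)


@pytest.fixture(scope="session")
def full_lattice():
    """The canonical 13-protofilament, 3-ring (39-dimer) build."""
    return ct.make_toy_lattice()


@pytest.fixture(scope="session")
def tailed_dimer(toy_dimer):
    spec = ct.TailSpec(target_role="alpha", seed=1)
    return ct.append_tail(toy_dimer, spec)


@pytest.fixture(scope="session")
def periodic_tailed_lattice(small_lattice):
    """Periodic tailed lattice: every tail has a trans minus-neighbour."""
    lattice, spec = small_lattice
    inf = ct.make_infinite(lattice, spec)
    return ct.append_tail(inf, ct.TailSpec(target_role="alpha", seed=1)), spec


def brute_force_salt_bridges(frame, topology, criterion, tail_sel, body_sel, box):
    """Independent all-pairs oracle for salt-bridge detection.

    Enumerates every donor-acceptor atom pair and, under axial
    periodicity, takes the minimum over the explicit -1/0/+1 image
    translations — no neighbour lists, no shared code path with the
    implementation under test.
    """
    from cttaccess.contacts import (
        DONOR_ATOMS,
        SIDECHAIN_ACCEPTOR_ATOMS,
        TERMINAL_ACCEPTOR_ATOMS,
    )

    def is_acceptor(i, selection):
        rn, an = str(topology.res_name[i]), str(topology.atom_name[i])
        if an in SIDECHAIN_ACCEPTOR_ATOMS.get(rn, ()):
            return True
        if an in TERMINAL_ACCEPTOR_ATOMS:
            key = (str(topology.chain_id[i]), int(topology.res_id[i]))
            for j in selection:
                if (str(topology.chain_id[j]), int(topology.res_id[j])) == key \
                        and str(topology.atom_name[j]) == "OXT":
                    return True
        return False

    acceptors = [i for i in tail_sel if is_acceptor(i, tail_sel)]
    donors = [
        i for i in body_sel
        if str(topology.atom_name[i])
        in DONOR_ATOMS.get(str(topology.res_name[i]), ())
    ]
    shifts = [np.zeros(3)]
    if box is not None and box.mode == "axial_periodic":
        shifts += [box.axial_length * box.axis, -box.axial_length * box.axis]
    contacts = set()
    for ia in acceptors:
        for idn in donors:
            d = min(
                np.linalg.norm(frame[ia] - (frame[idn] + s)) for s in shifts
            )
            if d <= criterion.cutoff:
                contacts.add((
                    str(topology.chain_id[ia]), int(topology.res_id[ia]),
                    str(topology.chain_id[idn]), int(topology.res_id[idn]),
                ))
    return contacts
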