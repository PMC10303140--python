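import numpy as np
import pytest

from deccp.integrals import make_hubbard_chain, make_localized_random
from deccp.scf import mo_transform, run_rhf


@pytest.fixture(scope="session")
def hubbard_dimer_u2():
    """2-site Hubbard chain, t=1, U=2: the standard small CP fixture."""
    s = make_hubbard_chain(2, 2, 1.0, 2.0)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    return s, scf, h_mo, g_mo


@pytest.fixture(scope="session")
def hubbard_dimer_u4():
    s = make_hubbard_chain(2, 2, 1.0, 4.0)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    return s, scf, h_mo, g_mo


@pytest.fixture(scope="session")
def small_random():
    """2 sites x 2 orbitals, 4 electrons: FCI-sized random local system."""
    s = make_localized_random(2, 2, 4, 2.0, seed=4)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    assert scf.converged and scf.homo_lumo_gap > 0.1
    return s, scf, h_mo, g_mo


@pytest.fixture(scope="session")
def medium_random():
    """4 sites x 2 orbitals, 4 electrons: DEC-sized random local system."""
    s = make_localized_random(4, 2, 4, 2.0, seed=3)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    assert scf.converged and scf.homo_lumo_gap > 0.1
    return s, scf, h_mo, g_mo


@pytest.fixture(scope="session")
def dec_fixture_6():
    """6 sites x 2 orbitals, 6 electrons: the exact-partition fixture."""
    s = make_localized_random(6, 2, 6, 2.0, seed=3)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    assert scf.converged and scf.homo_lumo_gap > 0.1
    return s, scf, h_mo, g_mo


@pytest.fixture(scope="session")
def reference_fixture_8():
    """The packaged reference system: 8 sites x 2 orbitals, 8 electrons,
    locality decay 2 / angstrom, seed 7."""
    s = make_localized_random(8, 2, 8, 2.0, seed=7)
    scf = run_rhf(s)
    h_mo, g_mo = mo_transform(s, scf.C)
    assert scf.converged and scf.homo_lumo_gap > 0.1
    return s, scf, h_mo, g_mo


def localized_setup(s, scf):
    """Localized orbitals plus local-basis integrals and Fock matrix."""
    from deccp.localization import build_local_orbitals
    lo = build_local_orbitals(scf, s)
    _, g_loc = mo_transform(s, lo.C_loc)
    F_site = scf.C @ np.diag(scf.eps) @ scf.C.T
    F_loc = lo.C_loc.T @ F_site @ lo.C_loc
    return lo, g_loc, F_loc
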