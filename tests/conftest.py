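"""Shared fixtures: reference geometry, drug library, and synthetic systems."""

import numpy as np
import pytest

from lobulepk import build_lobule, build_grid, load_drug_library
from lobulepk.engine import build_system
from lobulepk.kinetics import InteractionTable
from lobulepk.pbpk import Regimen


@pytest.fixture(scope="session")
def geometry():
    return build_lobule()


@pytest.fixture(scope="session")
def library():
    return load_drug_library()


@pytest.fixture(scope="session")
def grid(library):
    return build_grid(library.geometry, 10)


@pytest.fixture()
def inert_system_factory(library):
    """Build a whole-body system for midazolam with all elimination off.

    The drug still distributes, absorbs and exchanges, but nothing is
    metabolised or excreted, so total drug amount is conserved: the
    closed-system oracle for mass-balance and linearity checks.
    """

    def make(doses, fa=1.0, ka=1.16):
        regs = [Regimen(Fa=fa, ka=ka, doses=doses)]
        system = build_system(library, ["midazolam"], regs)
        nC, nE = 1, len(library.physiology.enzyme_names)
        empty = InteractionTable.empty(nC, nE)
        system.liver.table = empty
        system.table_gut = empty
        system.body.CL_int_R = np.zeros(nC)
        return system

    return make
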