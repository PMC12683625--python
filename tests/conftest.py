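"""Shared fixtures.

The expensive end-to-end dimerization run (density-of-states estimation plus
production sampling for an 8-residue homopolymer dimer) is session-scoped and
shared by every test that needs it.
"""

from __future__ import annotations

import pytest

from pepdimer.params import load_parameters
from pepdimer.topology import build_topology


@pytest.fixture(scope="session")
def params():
    return load_parameters("reference-simplified")


@pytest.fixture(scope="session")
def tri_system(params):
    """Small 3-residue monomer system for energy-model tests."""
    from pepdimer.model import System

    topo = build_topology("AAA", params)
    return System([topo], params, 60.0)


DIMER_SEED = 7


@pytest.fixture(scope="session")
def dimer_run():
    """Scaled-down dimerization study: estimate ln g(U), then production.

    Runs under the fixed study conditions of
    :mod:`pepdimer.dimer_study`; shared by every end-to-end test.
    """
    from pepdimer.dimer_study import run_dimer_study

    return run_dimer_study(DIMER_SEED)
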