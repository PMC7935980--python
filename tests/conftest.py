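"""Shared fixtures: landscape tables and simulated critical frequencies.

The dipole-table builds and critical-frequency bisections are the expensive
pieces; they are session-scoped and computed lazily so each geometry is
simulated exactly once across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from nlmsim.dynamics import BeadSpec, DimerSpec, PeriodicLandscapeTable, find_critical_frequency
from nlmsim.fields import ExternalFieldSpec
from nlmsim.geometry import standard_array


@pytest.fixture(scope="session")
def ext():
    return ExternalFieldSpec()


class _LazyTables:
    def __init__(self):
        self._tables: dict[str, PeriodicLandscapeTable] = {}

    def __call__(self, code: str) -> PeriodicLandscapeTable:
        if code not in self._tables:
            self._tables[code] = PeriodicLandscapeTable(standard_array(code))
        return self._tables[code]


@pytest.fixture(scope="session")
def tables():
    """tables('C') -> periodic landscape table for that geometry (cached)."""
    return _LazyTables()


class _LazyCharacteristics:
    """Simulated critical frequencies per (geometry, species), bisected once."""

    def __init__(self, ext, tables):
        self._ext = ext
        self._tables = tables
        self._fc: dict[tuple[str, str], float] = {}

    def f_c(self, code: str, species: str) -> float:
        key = (code, species)
        if key not in self._fc:
            particle = DimerSpec() if species == "dimer" else BeadSpec()
            self._fc[key] = find_critical_frequency(
                particle,
                standard_array(code),
                self._ext,
                table=self._tables(code),
            )
        return self._fc[key]


@pytest.fixture(scope="session")
def sim_fc(ext, tables):
    return _LazyCharacteristics(ext, tables)
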