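"""Shared fixtures: one backend and one self-verified scenario set per session."""

from __future__ import annotations

import pytest

from srnatim import NearestNeighborBackend, fixture_set


@pytest.fixture(scope="session")
def backend():
    return NearestNeighborBackend()


@pytest.fixture(scope="session")
def scenarios():
    """The bundled synthetic scenario set for seed 1 (self-verified)."""
    return fixture_set(1)


@pytest.fixture(scope="session")
def scenario_by_label(scenarios):
    return {sc.label: sc for sc in scenarios}
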