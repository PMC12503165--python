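"""Shared fixtures: the default synthetic community and one pipeline run.

Both are expensive enough to share session-wide; all tests treat them as
read-only.
"""

from __future__ import annotations

import pytest

from ai2net.pipeline import run_pipeline
from ai2net.references import default_refsets
from ai2net.synthdata import default_plan, generate_community

COMMUNITY_SEED = 1


@pytest.fixture(scope="session")
def community():
    """(genomes, truth manifest) for the default 60-species plan."""
    return generate_community(default_plan(seed=COMMUNITY_SEED))


@pytest.fixture(scope="session")
def genomes(community):
    return community[0]


@pytest.fixture(scope="session")
def manifest(community):
    return community[1]


@pytest.fixture(scope="session")
def pipeline_result(genomes):
    return run_pipeline(genomes)


@pytest.fixture(scope="session")
def refsets():
    return default_refsets()
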