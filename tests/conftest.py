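import numpy as np
import pytest
from hypothesis import settings

from blastbin import FixtureSpec, Hierarchy, ReferenceData, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def seed_tree() -> Hierarchy:
    """Tiny multi-labeled SEED-style tree: RoleB labels leaves in S1 and S2."""
    parent = {
        "root": "root",
        "S1": "root",
        "S2": "root",
        "L1": "S1",
        "L2": "S1",
        "L3": "S2",
        "L4": "S2",
    }
    roles = {"L1": "RoleA", "L2": "RoleB", "L3": "RoleB", "L4": "RoleC"}
    return Hierarchy(parent, leaf_role=roles)


@pytest.fixture
def taxonomy() -> Hierarchy:
    """root -> {A -> {B, C}, D -> {E}}."""
    return Hierarchy(
        {"root": "root", "A": "root", "D": "root", "B": "A", "C": "A", "E": "D"}
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One generated noise-free fixture, shared across tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=11)
    paths = generate(spec, outdir)
    return spec, paths, ReferenceData.load(outdir)


def make_hits(read_id, pairs):
    """(subject, score) pairs -> ReadHits with fixed identity/evalue."""
    from blastbin import BlastHit, ReadHits

    return ReadHits(
        read_id,
        [
            BlastHit(read_id, acc, identity=90.0, evalue=1e-10, bit_score=score)
            for acc, score in pairs
        ],
    )


@pytest.fixture
def hits_factory():
    return make_hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
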