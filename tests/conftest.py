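import random

import pytest

from gmapkit import assemble
from gmapkit.fixtures import (
    FixtureSpec,
    generate_fixture_backbone,
    generate_fixture_parts,
)


def rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def fixture_spec():
    # moderate core sizes keep the suite fast; architecture is the default
    # lentiviral-style 1-5 backbone with a 469 bp spacer
    return FixtureSpec(seed=11, core_length_range=(150, 500))


@pytest.fixture(scope="session")
def parts(fixture_spec):
    return generate_fixture_parts(fixture_spec)


@pytest.fixture(scope="session")
def parts_by_slot(parts):
    return {p.slot: p for p in parts}


@pytest.fixture(scope="session")
def backbone_fixture(fixture_spec):
    return generate_fixture_backbone(fixture_spec)


@pytest.fixture(scope="session")
def four_part_product(parts_by_slot, backbone_fixture):
    frags = [parts_by_slot[s] for s in ("pA", "gA", "pB", "gB")]
    return assemble(frags, backbone_fixture.backbone)
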