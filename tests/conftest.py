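import numpy as np
import pytest

from quicklama import (
    FixtureSpec,
    blunt_duplex,
    design_primer_set,
    fragment_plan,
    phosphorylate,
    random_target,
)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def target_1kb():
    """Seeded 1 kb synthetic target used across the suite."""
    return random_target(FixtureSpec(length=1000, seed=1))


@pytest.fixture(scope="session")
def plan_1kb(target_1kb):
    """Primer set + fragment plan for the 1 kb target."""
    ps = design_primer_set(target_1kb.sequence)
    return target_1kb.sequence, ps, fragment_plan(target_1kb.sequence, ps)


@pytest.fixture(scope="session")
def ae_pair(plan_1kb):
    """Phosphorylated fragment A / fragment E duplex pair."""
    _, _, plan = plan_1kb
    return (
        phosphorylate(blunt_duplex(plan.frag_a)),
        phosphorylate(blunt_duplex(plan.frag_e)),
    )
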