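import numpy as np
import pytest

from ragdel import annotate as ann
from ragdel import junctions as jx
from ragdel import simulate as sim

BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), p=BACKGROUND, size=n))


@pytest.fixture(scope="session")
def scanner():
    """Default motif scanner (heptamer, nonamer, both full-RSS variants)."""
    return ann.build_scanner()


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort under default study conditions."""
    return sim.simulate_cohort(sim.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def annotated_cohort(default_cohort, scanner):
    """Annotations for the default cohort, junctions attached."""
    cohort = default_cohort
    jx.resolve_all(cohort.deletions, cohort.genome)
    annotations = ann.annotate_deletions(
        cohort.deletions, cohort.genome, cohort.regions, scanner
    )
    jx.attach_junctions(annotations, cohort.genome)
    return annotations
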