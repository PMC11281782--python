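import numpy as np
import pytest
from hypothesis import settings

import rag_offtarget as ro

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_small() -> ro.SimResult:
    """Default-sized synthetic sample used across modules."""
    return ro.simulate(ro.SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_cohort50() -> ro.SimResult:
    """Seed-fixed cohort of 50 RAG events, zero jitter, chew capped below 21 bp."""
    return ro.simulate(
        ro.SimConfig(
            seed=3,
            n_rag_events=50,
            n_crss=300,
            n_background_svs=20,
            breakpoint_jitter_bp=0,
            chew_max_bp=20,
        )
    )


@pytest.fixture(scope="session")
def random_genome() -> ro.GenomeSequences:
    """A 10 kb single-contig uniform-random genome (no planted motifs)."""
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    return ro.GenomeSequences({"chr1": seq})
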