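import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitopop as mp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_aln() -> mp.SequenceAlignment:
    """Alignment reconstructed from the published haplotype-by-locality counts."""
    return mp.table1_fixture()


@pytest.fixture(scope="session")
def table1_table(table1_aln) -> mp.HaplotypeTable:
    return mp.collapse_haplotypes(table1_aln)


def random_alignment(rng: np.random.Generator, n: int, L: int, n_pops: int = 1,
                     missing_rate: float = 0.0) -> mp.SequenceAlignment:
    """Small random alignment for property tests."""
    alphabet = "ACGT" + ("N-" if missing_rate > 0 else "")
    probs = None
    if missing_rate > 0:
        p = (1 - missing_rate) / 4
        probs = [p, p, p, p, missing_rate / 2, missing_rate / 2]
    seqs = [
        "".join(rng.choice(list(alphabet), size=L, p=probs)) for _ in range(n)
    ]
    pops = [f"P{rng.integers(n_pops) + 1}" for _ in range(n)]
    return mp.SequenceAlignment(
        ids=tuple(f"s{i}" for i in range(n)),
        populations=tuple(pops),
        sequences=tuple(seqs),
    )
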