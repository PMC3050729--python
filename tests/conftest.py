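import numpy as np
import pytest

from pbmscan import (
    EScoreTable,
    SyntheticTableSpec,
    build_dense_array,
    make_table,
)
from pbmscan.kmers import N_OCTAMERS, RC_CODES


@pytest.fixture(scope="session")
def clean_table():
    """Noise-free synthetic table with its ground-truth manifest."""
    return make_table(SyntheticTableSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_array(clean_table):
    table, _ = clean_table
    return build_dense_array(table)


@pytest.fixture(scope="session")
def noisy_table():
    """Synthetic table with measurement noise (default study conditions)."""
    return make_table(SyntheticTableSpec(noise_sd=0.02, seed=11))


def random_symmetric_table(rng: np.random.Generator, tf_name: str = "random") -> EScoreTable:
    """A valid (total, bounded, symmetric) table with i.i.d. uniform scores."""
    vals = rng.uniform(-0.5, 0.5, N_OCTAMERS)
    canonical = np.minimum(np.arange(N_OCTAMERS), RC_CODES)
    return EScoreTable(vals[canonical], tf_name=tf_name)


def uniform_table(score: float) -> EScoreTable:
    return EScoreTable(np.full(N_OCTAMERS, score), tf_name=f"uniform{score}")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def naive_profile(seq: str, table: EScoreTable, window: int) -> list[float]:
    """O(L*W) reference implementation of the moving-average profile."""
    out = []
    for i in range(len(seq) - window - 6):
        vals = []
        ok = True
        for j in range(window):
            octamer = seq[i + j : i + j + 8]
            if any(c not in "ACGT" for c in octamer):
                ok = False
                break
            vals.append(table.score(octamer))
        out.append(float(np.mean(vals)) if ok else float("nan"))
    return out
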