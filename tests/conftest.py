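import numpy as np
import pytest

import thermodesign as td
from thermodesign.msa import AMINO_ACIDS


@pytest.fixture
def planted_spec():
    """Synthetic study conditions: 50 sequences, consensus 0.8 vs wt 0.05."""
    return td.SyntheticSpec(
        seed=7,
        planted_consensus_sites=[
            td.PlantedSite(5, "V", "L"),
            td.PlantedSite(12, "A", "P"),
            td.PlantedSite(30, "T", "I"),
        ],
    )


@pytest.fixture
def planted_alignment(planted_spec):
    return td.generate_msa(planted_spec)


def random_alignment(rng, n_seqs=None, length=None, with_gaps=True):
    """A random alignment whose query row is gap-free at >= 1 position."""
    n = n_seqs or int(rng.integers(3, 12))
    L = length or int(rng.integers(2, 30))
    aa = list(AMINO_ACIDS)
    rows = []
    for i in range(n):
        chars = [str(rng.choice(aa)) for _ in range(L)]
        if with_gaps and i > 0:
            for j in range(L):
                if rng.random() < 0.15:
                    chars[j] = "-"
        rows.append((f"s{i}", "".join(chars)))
    rows[0] = ("query", rows[0][1])
    return td.Alignment(records=rows, query_id="query")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
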