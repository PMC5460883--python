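import itertools

import numpy as np
import pytest

from covhmm import SimConfig, SimEvent


def brute_force_posterior(e, pi0, T):
    """Exhaustive path-sum posterior: enumerate all 3^L state paths."""
    e = np.asarray(e, float)
    n = len(e)
    probs = np.zeros((n, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=n):
        p = pi0[path[0]] * e[0, path[0]]
        for t in range(1, n):
            p *= T[path[t - 1], path[t]] * e[t, path[t]]
        total += p
        for t, s in enumerate(path):
            probs[t, s] += p
    return probs / total


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def event_sim_config():
    """Small simulation with one event of each structural class."""
    return SimConfig(
        seed=7,
        n_genes=36,
        n_strains=4,
        events=(
            SimEvent("whole_gene", 4, 2.0, ("s01",)),
            SimEvent("chimera", 10, 2.0, ("s02",)),
            SimEvent("de_novo", 20, carriers=("s01",)),
            SimEvent("intergenic", carriers=("s03",)),
        ),
    )


MINIMAL_GFF = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
"""


@pytest.fixture
def minimal_gff(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(MINIMAL_GFF)
    return p
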