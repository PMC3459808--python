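import random

import numpy as np
import pytest

from mirsitescan import NucleotideSequence, UTRRecord, GenomicInterval
from mirsitescan.duplex import default_energy_parameters


@pytest.fixture(scope="session")
def params():
    return default_energy_parameters()


@pytest.fixture(scope="session")
def adam10_like_utr():
    """Synthetic stand-in UTR carrying the real ADAM10 3'UTR interval.

    The genomic anchor (chr15:58888510-58889745, 1236 nt) is the published
    transcript interval; the sequence itself is synthetic (seeded random),
    since only the coordinate arithmetic depends on it.
    """
    rng = random.Random(58888510)
    seq = "".join(rng.choice("ACGT") for _ in range(1236))
    return UTRRecord(
        "ADAM10_3UTR",
        NucleotideSequence(seq, "DNA"),
        GenomicInterval("chr15", 58888510, 58889745, "+"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(r, n):
    return "".join(r.choice(list("ACGU")) for _ in range(n))
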