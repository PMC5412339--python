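"""Shared fixtures: the two published guide sequences and small seeded
references with the protospacer embedded."""

from __future__ import annotations

import numpy as np
import pytest

from nhejscope import GuideRNA, make_reference

# protospacers recovered from the cloning-oligo pairs (scaffold G stripped)
GRNA1 = "GCCTCCGGGGACTGCCGTGC"
GRNA2 = "GGTTCGTGTCGCCGGCCCGC"

OLIGO_PAIRS = {
    "gRNA1": ("CACCGGCCTCCGGGGACTGCCGTGC", "CCGGAGGCCCCTGACGGCACGCAAA"),
    "gRNA2": ("CACCGGGTTCGTGTCGCCGGCCCGC", "CCCAAGCACAGCGGCCGGGCGCAAA"),
}


@pytest.fixture(scope="session")
def guide1() -> GuideRNA:
    return GuideRNA("gRNA1", GRNA1)


@pytest.fixture(scope="session")
def small_ref(guide1):
    """80-nt-flank reference with the gRNA1 protospacer embedded once."""
    return make_reference(80, guide1, "TGG", 80, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
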