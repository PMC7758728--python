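from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from quantmir.references import (Hairpin, MatureMiRNA, ReferenceSet,
                                 make_spikein_ladder, revcomp)
from quantmir.simlib import make_reference

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

_LETTERS = np.array(list("ACGT"))


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_LETTERS[rng.integers(0, 4, size=n)])


def stem_loop_hairpin(mature: str, rng: np.random.Generator,
                      tail: int = 0) -> tuple[Hairpin, MatureMiRNA]:
    """Perfect stem-loop with ``mature`` on the 3p arm, plus optional 3' tail."""
    loop = rand_seq(rng, 8)
    seq = revcomp(mature) + loop + mature + rand_seq(rng, tail)
    hp = Hairpin(id="hp", sequence=seq,
                 context3="A" + rand_seq(rng, 5))
    start = len(mature) + 8 + 1
    mat = MatureMiRNA(id="m", hairpin_id="hp", arm="3p", sequence=mature,
                      start=start, end=start + len(mature) - 1)
    return hp, mat


@pytest.fixture(scope="session")
def ref() -> ReferenceSet:
    """Default synthetic study reference: miR-35fam (8) + miR-51fam (6) +
    16 singletons, 20 piRNAs, the 8-oligo 500-fold spike-in ladder."""
    return make_reference(rng_seed=11)


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceSet:
    """Three-miRNA reference for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(42)
    matures, hairpins = [], {}
    for i in range(3):
        mat = rand_seq(rng, 22)
        loop = rand_seq(rng, 8)
        seq = revcomp(mat) + loop + mat
        hid = f"t{i}-pre"
        hairpins[hid] = Hairpin(id=hid, sequence=seq,
                                context3=rand_seq(rng, 1).replace("T", "A") + rand_seq(rng, 5))
        matures.append(MatureMiRNA(id=f"t{i}", hairpin_id=hid, arm="3p",
                                   sequence=mat, start=31, end=52))
    spikes = make_spikein_ladder(avoid=[m.sequence for m in matures], rng_seed=43)
    return ReferenceSet(matures=matures, hairpins=hairpins, pirnas={},
                        spikeins=spikes, families={})
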