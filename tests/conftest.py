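import numpy as np
import pytest

from silnas.ptm_catalog import load_atlas


@pytest.fixture(scope="session")
def human_atlas():
    return load_atlas("human")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_modified_sequence(rng, length=200, mod_rate=0.05, seq_id="rand"):
    """Random RNA with random (parent-base-consistent) modifications."""
    from silnas.digestion import ModifiedRnaSequence
    from silnas.ptm_catalog import MODIFICATION_ALPHABET

    residues = "".join(rng.choice(list("ACGU"), size=length))
    by_base = {}
    for code, mod in MODIFICATION_ALPHABET.items():
        by_base.setdefault(mod.parent_base, []).append(code)
    mods = {}
    for pos in range(1, length + 1):
        if rng.random() < mod_rate:
            codes = by_base[residues[pos - 1]]
            mods[pos] = codes[rng.integers(len(codes))]
    return ModifiedRnaSequence(seq_id, residues, mods)
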