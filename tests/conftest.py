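import numpy as np
import pytest

from bifanr.msa_io import Alignment, encode_sequence


def alignment_from_strings(seqs, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return Alignment(ids, np.vstack([encode_sequence(s) for s in seqs]))


@pytest.fixture
def toy_alignment():
    """4 sequences x 2 columns: col0 = (A,A,C,C), col1 = (D,D,E,E)."""
    return alignment_from_strings(["AD", "AD", "CE", "CE"])


@pytest.fixture
def random_small_alignments():
    """A handful of random small alignments (S <= 8, L <= 6) for oracle checks."""
    rng = np.random.default_rng(20240917)
    out = []
    for _ in range(4):
        S = rng.integers(4, 9)
        L = rng.integers(3, 7)
        mat = rng.integers(0, 21, size=(S, L))
        # keep at least one residue per column so weights are defined
        for j in range(L):
            if (mat[:, j] == 0).all():
                mat[0, j] = rng.integers(1, 21)
        out.append(Alignment([f"s{i}" for i in range(S)], mat))
    return out
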