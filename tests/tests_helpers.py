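"""Shared helpers for building random test inputs."""

import numpy as np

from vrflp.seqio import AlignedSet, SequenceRecord


def random_alignment(rng, n=None, length=None, p_gap=0.05, p_ambig=0.03):
    """A random alignment with occasional gaps and ambiguity codes, with at
    least one fully unambiguous column guaranteed."""
    n = n or int(rng.integers(2, 8))
    length = length or int(rng.integers(5, 40))
    bases = np.array(list("ACGT"))
    chars = bases[rng.integers(0, 4, size=(n, length))]
    noise = rng.random((n, length))
    chars[noise < p_gap] = "-"
    chars[(noise >= p_gap) & (noise < p_gap + p_ambig)] = "N"
    chars[:, 0] = bases[rng.integers(0, 4, size=n)]  # keep >= 1 clean column
    return AlignedSet(
        tuple(
            SequenceRecord(id=f"s{i + 1}", residues="".join(row))
            for i, row in enumerate(chars)
        )
    )
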