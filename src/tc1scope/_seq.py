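"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform A/C/G/T string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def substream(seed: int, *tags: int) -> np.random.Generator:
    """Independent, reproducible random substream for one operation.

    All randomness in the package flows from one integer seed per operation;
    tagged substreams keep operations independently reproducible.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(t) for t in tags)))


def encode(seq: str) -> np.ndarray:
    """DNA string as a uint8 array (ASCII codes), for vectorized comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
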