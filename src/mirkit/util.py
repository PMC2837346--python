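"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (returned as DNA)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def spawn_rng(seed: int, *salt: int) -> np.random.Generator:
    """Derive an independent generator from a base seed plus salt integers."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salt)]))
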