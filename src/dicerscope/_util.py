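"""Shared helpers: nucleotide arithmetic and seeded RNG derivation."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA-as-DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def derive_rng(seed: int, *tags: int) -> np.random.Generator:
    """A Generator deterministically derived from one global seed.

    Every stochastic stage draws from its own stream, keyed by small
    integer tags, so stages can be re-run or reordered without
    perturbing each other.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random nucleotide string."""
    return "".join(BASES[rng.integers(0, 4, size=length)])
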