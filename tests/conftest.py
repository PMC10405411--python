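import numpy as np
import pytest

from dicerscope.synthetic import (
    DicerModel,
    build_hairpin,
    build_minigenome,
    default_minigenome_spec,
    simulate_dicer_products,
)


@pytest.fixture(scope="session")
def minigenome():
    """Default minigenome: (sequences, genes)."""
    return build_minigenome(default_minigenome_spec(seed=5))


@pytest.fixture(scope="session")
def hairpin275():
    return build_hairpin(275, 79, seed=1)


@pytest.fixture(scope="session")
def hairpin_yield(hairpin275):
    """10,000 strict-stem duplexes with no background, seed 7."""
    model = DicerModel(
        size_weights={20: 0.1, 21: 0.6, 22: 0.3},
        loop_leak=0.0,
        background_fraction=0.0,
    )
    return simulate_dicer_products(hairpin275, model, 10_000, seed=7)


def brute_force_placements(read: str, references: dict[str, str], max_mismatch: int):
    """Independent oracle: exhaustive scan of every offset and strand.

    Returns the set of (reference, start, strand) at the minimal
    achievable mismatch count <= max_mismatch, mirroring best-stratum
    alignment semantics.
    """
    from dicerscope._util import revcomp

    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    rc_arr = np.frombuffer(revcomp(read).encode(), dtype=np.uint8)
    k = len(read)
    hits: list[tuple[int, tuple[str, int, str]]] = []
    for name, seq in references.items():
        ref_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(ref_arr) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, k)
        for arr, strand in ((read_arr, "+"), (rc_arr, "-")):
            mm = (windows != arr).sum(axis=1)
            for start in np.flatnonzero(mm <= max_mismatch):
                hits.append((int(mm[start]), (name, int(start), strand)))
    if not hits:
        return set(), None
    best = min(m for m, _ in hits)
    return {placement for m, placement in hits if m == best}, best
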