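"""Hairpin processing analysis.

Quantifies how a Dicer-processed inverted-repeat transcript shows up in
an sRNA library: the fraction of the library derived from the
double-stranded stem, per-size 5'-end positional profiles, and a
Fisher-exact scan that localises the stem/loop boundaries where sRNA
production drops.

The boundary test compares observed 5'-end counts in the two windows
flanking a candidate boundary against an equal-occupancy expectation
(w, w) in a 2x2 Fisher exact table; a scan over candidate positions
around each annotated loop edge returns the minimum-p position with
Bonferroni correction over the scanned positions. Because a hairpin's
two arms are perfect complements, every stem read maps to both arms
(one placement per strand); the scan therefore uses the strand-summed
profile, whose minus-strand 5' ends approach within ~2 nt of the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .align import PositionalProfile, SmallReadAlignment, five_prime_profile
from .synthetic.substrates import HairpinConstruct


@dataclass(frozen=True)
class StemLoopPartition:
    """Disjoint stem/loop intervals tiling ``[0, length)``."""

    stems: tuple[tuple[int, int], tuple[int, int]]
    loop: tuple[int, int]
    length: int

    def __post_init__(self) -> None:
        (s1, s2), loop = self.stems, self.loop
        covered = [s1, loop, s2]
        pos = 0
        for lo, hi in covered:
            if lo != pos or hi < lo:
                raise ValueError("stem/loop intervals must tile the construct")
            pos = hi
        if pos != self.length:
            raise ValueError("intervals do not cover the construct")

    @classmethod
    def from_construct(cls, construct: HairpinConstruct) -> "StemLoopPartition":
        return cls(construct.stem_intervals, construct.loop_interval, construct.length)


@dataclass(frozen=True)
class BoundaryCall:
    """Result of a boundary test at one candidate position."""

    boundary_position: int
    p_value: float
    window: int
    direction: str
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")


@dataclass(frozen=True)
class HairpinFraction:
    """Stem-derived share of the library, under both denominators."""

    of_total: float
    of_mapped: float
    stem_weight: float
    mapped_weight: float
    library_size: int


def _within_stems(a: SmallReadAlignment, partition: StemLoopPartition) -> bool:
    lo, hi = a.start, a.start + a.length
    return any(lo >= s and hi <= e for s, e in partition.stems)


def hairpin_fraction(
    alignments: list[SmallReadAlignment],
    partition: StemLoopPartition,
    library_size: int,
    reference: str = "hairpin",
) -> HairpinFraction:
    """Share of the library whose reads lie entirely within the stem.

    A read "originates from the dsRNA portion" iff its full placement
    interval is inside a stem interval. The primary denominator is the
    total library size; the mapped-read denominator is also reported.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    stem_w = 0.0
    mapped_w = 0.0
    for a in alignments:
        mapped_w += a.weight
        if a.reference == reference and _within_stems(a, partition):
            stem_w += a.weight
    of_mapped = stem_w / mapped_w if mapped_w > 0 else 0.0
    return HairpinFraction(stem_w / library_size, of_mapped, stem_w, mapped_w, library_size)


def loop_boundary_test(
    profile: PositionalProfile,
    boundary: int,
    window: int = 20,
    direction: str = "into_loop_from_left",
) -> BoundaryCall:
    """Two-sided Fisher exact test for a coverage step at ``boundary``.

    The 2x2 table opposes the observed strand-summed 5'-end counts in
    ``[b-w, b)`` and ``[b, b+w)`` (rounded to integers) to the
    equal-occupancy reference row (w, w).
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    combined = profile.combined()
    if combined.sum() == 0:
        raise ValueError("empty positional profile")
    n = len(combined)
    if boundary - window < 0 or boundary + window > n:
        raise ValueError("test windows extend beyond the construct")
    left = int(round(combined[boundary - window : boundary].sum()))
    right = int(round(combined[boundary : boundary + window].sum()))
    _, p = fisher_exact([[left, right], [window, window]], alternative="two-sided")
    return BoundaryCall(boundary, float(p), window, direction)


def scan_boundary(
    profile: PositionalProfile,
    partition: StemLoopPartition,
    window: int = 20,
) -> dict[str, BoundaryCall]:
    """Best boundary call per loop edge, Bonferroni-corrected.

    Evaluates :func:`loop_boundary_test` at every position within
    ``+-window`` of each annotated loop edge and keeps the minimum-p
    position per edge; ``p_adjusted`` multiplies by the number of
    scanned positions.
    """
    loop_lo, loop_hi = partition.loop
    if loop_hi - loop_lo < 1:
        raise ValueError("loop length must be >= 1")
    n = len(profile.combined())
    out: dict[str, BoundaryCall] = {}
    for edge, direction in (
        (loop_lo, "into_loop_from_left"),
        (loop_hi, "into_loop_from_right"),
    ):
        candidates = [
            b
            for b in range(edge - window, edge + window + 1)
            if b - window >= 0 and b + window <= n
        ]
        if not candidates:
            raise ValueError("no candidate boundary fits within the construct")
        calls = [loop_boundary_test(profile, b, window, direction) for b in candidates]
        best = min(calls, key=lambda c: (c.p_value, abs(c.boundary_position - edge)))
        out[direction] = BoundaryCall(
            best.boundary_position,
            best.p_value,
            window,
            direction,
            p_adjusted=min(1.0, best.p_value * len(candidates)),
        )
    return out


def per_size_profiles(
    alignments: list[SmallReadAlignment],
    reference: str,
    reference_length: int,
    sizes: tuple[int, ...] = (20, 21, 22),
) -> dict[int, PositionalProfile]:
    """One 5'-end profile per product size."""
    return {
        k: five_prime_profile(alignments, reference, reference_length, size_filter=(k,))
        for k in sizes
    }


def plot_profiles(
    profiles: dict[int, PositionalProfile],
    partition: StemLoopPartition,
    path,
    sqrt_scale: bool = True,
) -> None:
    """Presentation-only stacked positional plot (square-root y scale).

    Never alters stored counts; purely an output artifact.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(profiles), 1, sharex=True, figsize=(8, 2 * len(profiles)))
    if len(profiles) == 1:
        axes = [axes]
    for ax, (k, prof) in zip(np.atleast_1d(axes), sorted(profiles.items())):
        plus, minus = prof.plus, prof.minus
        if sqrt_scale:  # display transform only; stored counts untouched
            plus, minus = np.sqrt(plus), np.sqrt(minus)
        ax.plot(plus, label="+", lw=0.8)
        ax.plot(-minus, label="-", lw=0.8)
        for edge in partition.loop:
            ax.axvline(edge, color="red", lw=0.8)
        ax.set_ylabel(f"{k} nt")
        ax.legend(loc="upper right", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
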