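"""Dicer substrates outside the genome: the inverted-repeat hairpin and
the defective-interfering (DI) replicon.

The hairpin models an inducible silencing construct: two perfectly
complementary arms separated by an intron-derived loop, so the mature
transcript folds into a near-perfect stem with a single-stranded loop.
The replicon models a small subviral RNA amplified by a viral replicase:
it accumulates single-nucleotide variants at a fixed per-site frequency
and is largely shielded from Dicer inside replication membranes, which
the ``accessibility`` parameter captures.
"""

from __future__ import annotations

from dataclasses import dataclass

from .._util import derive_rng, random_sequence, revcomp


@dataclass(frozen=True)
class HairpinConstruct:
    """An inverted-repeat transcript: arm + loop + reverse complement(arm).

    ``stem_intervals`` are the two half-open arm intervals on the
    transcript, ``loop_interval`` the single-stranded segment between
    them. The default geometry (275-nt arms, 79-nt loop) yields a
    629-nt transcript.
    """

    arm_length: int
    loop_length: int
    arm_sequence: str
    loop_sequence: str

    @property
    def transcript_sequence(self) -> str:
        return self.arm_sequence + self.loop_sequence + revcomp(self.arm_sequence)

    @property
    def length(self) -> int:
        return 2 * self.arm_length + self.loop_length

    @property
    def stem_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a, l = self.arm_length, self.loop_length
        return ((0, a), (a + l, 2 * a + l))

    @property
    def loop_interval(self) -> tuple[int, int]:
        a = self.arm_length
        return (a, a + self.loop_length)


def build_hairpin(arm_length: int = 275, loop_length: int = 79, seed: int = 0) -> HairpinConstruct:
    """Build a hairpin construct with random arm and loop sequence.

    Raises ``ValueError`` for negative arm length or a loop shorter than
    1 nt (a physical hairpin needs a turn).
    """
    if arm_length < 0:
        raise ValueError("arm_length must be >= 0")
    if loop_length < 1:
        raise ValueError("loop_length must be >= 1")
    rng = derive_rng(seed, 102)
    arm = random_sequence(rng, arm_length)
    loop = random_sequence(rng, loop_length)
    return HairpinConstruct(arm_length, loop_length, arm, loop)


@dataclass
class RepliconModel:
    """A replicase-amplified RNA with per-site variation and low Dicer access.

    ``per_site_mutation_rate`` is an independent substitution probability
    per nucleotide per molecule (default 0.03, the observed variant
    frequency in replicon progeny); ``accessibility`` is the probability
    that a given molecule is exposed to Dicer at all (default 0.01,
    i.e. strongly membrane-protected).
    """

    sequence: str
    per_site_mutation_rate: float = 0.03
    accessibility: float = 0.01

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("replicon sequence must be non-empty")
        if not 0.0 <= self.per_site_mutation_rate <= 1.0:
            raise ValueError("per_site_mutation_rate outside [0,1]")
        if not 0.0 <= self.accessibility <= 1.0:
            raise ValueError("accessibility outside [0,1]")

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_replicon(
    length: int = 477,
    per_site_mutation_rate: float = 0.03,
    accessibility: float = 0.01,
    seed: int = 0,
) -> RepliconModel:
    """A random replicon at the default 477-nt scenario."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = derive_rng(seed, 103)
    return RepliconModel(random_sequence(rng, length), per_site_mutation_rate, accessibility)
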