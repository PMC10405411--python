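"""Generative model of Dicer processing.

Dicer cleaves double-stranded RNA into short duplexes whose two strands
have equal length (20–22 nt here) and whose 3' ends each protrude by
exactly 2 nt — the chemical signature that distinguishes genuine Dicer
products from degradation fragments. The simulator draws cut positions
uniformly over the double-stranded region of a substrate, emits one
sequenced strand per duplex, and mixes in a configurable fraction of
non-Dicer background degradation reads (uniform 17–24 nt).

Substrates:

* :class:`~dicerscope.synthetic.substrates.HairpinConstruct` — the stem
  is the dsRNA region; the loop is excluded unless ``loop_leak`` lets a
  draw treat the whole stem+loop as double-stranded.
* :class:`DuplexRegion` — an arbitrary dsRNA window on a longer
  sequence (a genomic sense/antisense overlap, or the whole replicon).

All coordinates are 0-based half-open on the substrate's plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import derive_rng, random_sequence, revcomp
from .genome import GeneModel
from .substrates import HairpinConstruct, RepliconModel

BACKGROUND_SIZES = np.arange(17, 25)  # degradation fragment lengths


@dataclass
class DicerModel:
    """Parameters of duplex production.

    ``size_weights`` maps product size to probability (must sum to 1);
    ``overhang`` is the 3' protrusion in nt and is fixed at 2;
    ``loop_leak`` is the probability that a hairpin draw treats the loop
    as double-stranded (0 = strict loop exclusion, 1 = uniform
    processing across stem and loop); ``strand_emission`` is the
    probability of sequencing the plus-sense strand of a duplex;
    ``background_fraction`` is the share of non-Dicer degradation reads.
    """

    size_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.1, 21: 0.6, 22: 0.3}
    )
    overhang: int = 2
    loop_leak: float = 0.0
    strand_emission: float = 0.5
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        if abs(sum(self.size_weights.values()) - 1.0) > 1e-9:
            raise ValueError("size_weights must sum to 1")
        if any(w < 0 for w in self.size_weights.values()):
            raise ValueError("size_weights must be non-negative")
        if self.overhang != 2:
            raise ValueError("Dicer products carry a fixed 2-nt 3' overhang")
        for name in ("loop_leak", "strand_emission", "background_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0,1]")

    def sizes_and_probs(self) -> tuple[np.ndarray, np.ndarray]:
        sizes = np.array(sorted(self.size_weights))
        probs = np.array([self.size_weights[k] for k in sizes], dtype=float)
        return sizes, probs

    @property
    def max_size(self) -> int:
        return max(k for k, w in self.size_weights.items() if w > 0)


@dataclass(frozen=True)
class DuplexRegion:
    """A double-stranded window ``[ds_start, ds_end)`` on ``sequence``."""

    name: str
    sequence: str
    ds_start: int
    ds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.ds_start <= self.ds_end <= len(self.sequence)):
            raise ValueError(f"region {self.name}: ds interval out of bounds")


@dataclass(frozen=True)
class Duplex:
    """One siRNA duplex in plus-strand coordinates of its substrate.

    ``plus_interval`` covers the plus-sense strand, ``minus_interval``
    the plus-strand footprint of the complementary strand; the 2-nt
    offset between them realises the two 3' overhangs.
    """

    substrate: str
    plus_interval: tuple[int, int]
    minus_interval: tuple[int, int]
    size: int


@dataclass(frozen=True)
class ProvenanceRecord:
    """Ground truth for one emitted read."""

    substrate: str
    start: int
    end: int
    strand: str
    n_mutations: int = 0
    source: str = "duplex"


@dataclass
class ReadSet:
    """Emitted reads plus complete per-read ground truth."""

    reads: list[tuple[str, str, str]]  # (id, sequence, quality)
    provenance: dict[str, ProvenanceRecord]

    def __post_init__(self) -> None:
        missing = [rid for rid, _, _ in self.reads if rid not in self.provenance]
        if missing:
            raise ValueError(f"reads without provenance: {missing[:3]}")

    def sequences(self) -> dict[str, str]:
        return {rid: seq for rid, seq, _ in self.reads}

    def extend(self, other: "ReadSet") -> None:
        dup = self.provenance.keys() & other.provenance.keys()
        if dup:
            raise ValueError(f"duplicate read ids: {sorted(dup)[:3]}")
        self.reads.extend(other.reads)
        self.provenance.update(other.provenance)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class DicerYield:
    """Duplexes cut from a substrate and the reads sequenced from them."""

    duplexes: list[Duplex]
    reads: ReadSet


def _qual(length: int) -> str:
    # constant maximal quality: qualities are never used downstream
    return "I" * length


def _background_reads(
    rng: np.random.Generator,
    n: int,
    pool: list[tuple[str, str]],
    prefix: str,
) -> ReadSet:
    """Degradation fragments drawn uniformly over pool nucleotides."""
    reads: list[tuple[str, str, str]] = []
    prov: dict[str, ProvenanceRecord] = {}
    if n == 0:
        return ReadSet(reads, prov)
    usable = [(name, seq) for name, seq in pool if len(seq) >= int(BACKGROUND_SIZES.max())]
    if not usable:
        raise ValueError("background pool has no sequence >= 24 nt")
    weights = np.array([len(seq) for _, seq in usable], dtype=float)
    picks = rng.choice(len(usable), size=n, p=weights / weights.sum())
    lens = rng.choice(BACKGROUND_SIZES, size=n)
    for i in range(n):
        name, seq = usable[picks[i]]
        ln = int(lens[i])
        s = int(rng.integers(0, len(seq) - ln + 1))
        rid = f"{prefix}_bg{i:06d}"
        reads.append((rid, seq[s : s + ln], _qual(ln)))
        prov[rid] = ProvenanceRecord(name, s, s + ln, "+", 0, "background")
    return ReadSet(reads, prov)


def simulate_dicer_products(
    substrate: HairpinConstruct | DuplexRegion,
    model: DicerModel,
    n: int,
    seed: int,
    background_pool: list[tuple[str, str]] | None = None,
    read_prefix: str = "hp",
    substrate_name: str | None = None,
) -> DicerYield:
    """Cut ``n`` reads' worth of products from one substrate.

    Duplex cut positions are uniform over the double-stranded region; a
    ``background_fraction`` share of the reads are degradation fragments
    drawn from ``background_pool`` (by default an unrelated decoy
    transcript, so background never maps to the substrate).

    Raises ``ValueError`` when products are requested from a substrate
    with no usable double-stranded region.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = derive_rng(seed, 104)
    n_bg = int(rng.binomial(n, model.background_fraction)) if n else 0
    n_prod = n - n_bg

    if background_pool is None:
        background_pool = [("decoy", random_sequence(rng, 2000))]

    duplexes: list[Duplex] = []
    reads: list[tuple[str, str, str]] = []
    prov: dict[str, ProvenanceRecord] = {}

    if n_prod > 0:
        sizes_arr, probs = model.sizes_and_probs()
        k = sizes_arr[rng.choice(len(sizes_arr), size=n_prod, p=probs)]
        if isinstance(substrate, HairpinConstruct):
            a, l = substrate.arm_length, substrate.loop_length
            name = substrate_name or "hairpin"
            t = substrate.transcript_sequence
            lt = len(t)
            if a - model.max_size < 2:
                raise ValueError("hairpin has no usable double-stranded region")
            leak = rng.random(n_prod) < model.loop_leak
            high = np.where(leak, a + l - k, a - k)  # inclusive upper bound for c
            c = rng.integers(2, high + 1)
            emit_plus = rng.random(n_prod) < model.strand_emission
            for i in range(n_prod):
                ci, ki = int(c[i]), int(k[i])
                duplexes.append(
                    Duplex(name, (ci, ci + ki), (ci - 2, ci + ki - 2), ki)
                )
                rid = f"{read_prefix}_{i:06d}"
                if emit_plus[i]:
                    s, e = ci, ci + ki
                else:
                    # complementary strand sits on the mirror arm of the
                    # same transcript, so the read is a plus-sense substring
                    s = lt + 2 - ci - ki
                    e = s + ki
                reads.append((rid, t[s:e], _qual(ki)))
                prov[rid] = ProvenanceRecord(name, s, e, "+", 0, "duplex")
        else:
            name = substrate_name or substrate.name
            seq = substrate.sequence
            lo, hi = substrate.ds_start, substrate.ds_end
            if hi - lo < model.max_size + 2:
                raise ValueError(f"region {name}: double-stranded region too short")
            c = rng.integers(lo + 2, hi - k + 1)
            emit_plus = rng.random(n_prod) < model.strand_emission
            for i in range(n_prod):
                ci, ki = int(c[i]), int(k[i])
                duplexes.append(
                    Duplex(name, (ci, ci + ki), (ci - 2, ci + ki - 2), ki)
                )
                rid = f"{read_prefix}_{i:06d}"
                if emit_plus[i]:
                    reads.append((rid, seq[ci : ci + ki], _qual(ki)))
                    prov[rid] = ProvenanceRecord(name, ci, ci + ki, "+", 0, "duplex")
                else:
                    s, e = ci - 2, ci + ki - 2
                    reads.append((rid, revcomp(seq[s:e]), _qual(ki)))
                    prov[rid] = ProvenanceRecord(name, s, e, "-", 0, "duplex")
    elif n > 0 and model.background_fraction == 0.0:
        raise ValueError("no products requested and no background configured")

    out = ReadSet(reads, prov)
    out.extend(_background_reads(rng, n_bg, background_pool, read_prefix))
    return DicerYield(duplexes, out)


def simulate_replicon_reads(
    model: RepliconModel,
    dicer: DicerModel,
    n_molecules: int,
    seed: int,
    read_prefix: str = "di",
    substrate_name: str = "replicon",
) -> ReadSet:
    """Dicer reads from a replicating, membrane-protected replicon.

    Each molecule is independently mutated at ``per_site_mutation_rate``
    per site; only an ``accessibility`` fraction of molecules is exposed
    to Dicer, and each exposed molecule yields one duplex read. Mutation
    counts within each read are recorded in provenance.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    rng = derive_rng(seed, 105)
    ln = model.length
    sizes_arr, probs = dicer.sizes_and_probs()
    if ln < dicer.max_size + 2:
        raise ValueError("replicon shorter than one duplex")
    exposed = np.flatnonzero(rng.random(n_molecules) < model.accessibility)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    bases = "ACGT"
    reads: list[tuple[str, str, str]] = []
    prov: dict[str, ProvenanceRecord] = {}
    for j, _mol in enumerate(exposed):
        if model.per_site_mutation_rate > 0:
            mut_pos = np.flatnonzero(rng.random(ln) < model.per_site_mutation_rate)
        else:
            mut_pos = np.empty(0, dtype=int)
        if mut_pos.size:
            chars = list(model.sequence)
            shifts = rng.integers(1, 4, size=mut_pos.size)
            for p, sh in zip(mut_pos, shifts):
                chars[p] = bases[(base_idx[chars[p]] + int(sh)) % 4]
            mseq = "".join(chars)
        else:
            mseq = model.sequence
        k = int(sizes_arr[rng.choice(len(sizes_arr), p=probs)])
        c = int(rng.integers(2, ln - k + 1))
        rid = f"{read_prefix}_{j:06d}"
        if rng.random() < dicer.strand_emission:
            s, e, strand = c, c + k, "+"
            seq = mseq[s:e]
        else:
            s, e, strand = c - 2, c + k - 2, "-"
            seq = revcomp(mseq[s:e])
        n_mut = int(np.count_nonzero((mut_pos >= s) & (mut_pos < e)))
        reads.append((rid, seq, _qual(k)))
        prov[rid] = ProvenanceRecord(substrate_name, s, e, strand, n_mut, "replicon")
    return ReadSet(reads, prov)


def dsrna_regions(
    genome: dict[str, str],
    genes: list[GeneModel],
    readthrough_extension: int = 300,
) -> list[tuple[DuplexRegion, float, str]]:
    """Double-stranded windows implied by the annotation.

    Returns ``(region, weight, chromosome)`` triples. Sense/antisense
    pairs contribute their overlap; convergent readthrough pairs
    contribute the intersection of their extended transcripts;
    hidden-antisense genes contribute their full interval down-weighted
    by the antisense transcription fraction.
    """
    regions: list[tuple[DuplexRegion, float, str]] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if a.chromosome != b.chromosome or a.strand == b.strand:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo < hi:
                regions.append(
                    (
                        DuplexRegion(f"as:{a.id}|{b.id}", genome[a.chromosome], lo, hi),
                        float(hi - lo),
                        a.chromosome,
                    )
                )
                continue
            # convergent non-overlapping pair: plus gene upstream of minus gene
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            if plus.end <= minus.start and minus.start - plus.end <= 200:
                lo = max(plus.start, minus.start - readthrough_extension)
                hi = min(minus.end, plus.end + readthrough_extension)
                if hi - lo > 0:
                    regions.append(
                        (
                            DuplexRegion(
                                f"rt:{plus.id}|{minus.id}", genome[plus.chromosome], lo, hi
                            ),
                            float(hi - lo),
                            plus.chromosome,
                        )
                    )
    for g in genes:
        if g.gene_class == "hidden_antisense" and g.hidden_antisense_fraction > 0:
            regions.append(
                (
                    DuplexRegion(f"ha:{g.id}", genome[g.chromosome], g.start, g.end),
                    g.length * g.hidden_antisense_fraction,
                    g.chromosome,
                )
            )
    return regions


def simulate_genome_srna(
    genome: dict[str, str],
    genes: list[GeneModel],
    model: DicerModel,
    n_reads: int,
    seed: int,
    readthrough_extension: int = 300,
    read_prefix: str = "gn",
) -> ReadSet:
    """A genome-wide sRNA library: Dicer duplexes from every dsRNA-forming
    locus plus degradation background from expressed transcripts.

    Dicer reads are allocated across dsRNA regions in proportion to
    region weight (length, scaled by antisense level for hidden loci);
    background reads are drawn from transcripts in proportion to
    ``baseline_expression x length``, on the transcript's own strand.
    Provenance regions carry chromosome coordinates.
    """
    rng = derive_rng(seed, 106)
    regions = dsrna_regions(genome, genes, readthrough_extension)
    n_bg = int(rng.binomial(n_reads, model.background_fraction)) if n_reads else 0
    n_ds = n_reads - n_bg
    reads: list[tuple[str, str, str]] = []
    prov: dict[str, ProvenanceRecord] = {}
    if n_ds > 0:
        if not regions:
            raise ValueError("no double-stranded regions in annotation")
        w = np.array([wt for _, wt, _ in regions], dtype=float)
        alloc = rng.multinomial(n_ds, w / w.sum())
        for (region, _wt, chrom), n_r in zip(regions, alloc):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            y = simulate_dicer_products(
                region,
                DicerModel(
                    size_weights=model.size_weights,
                    strand_emission=model.strand_emission,
                    background_fraction=0.0,
                ),
                int(n_r),
                sub_seed,
                read_prefix=f"{read_prefix}_{region.name}",
                substrate_name=chrom,
            )
            rs = y.reads
            for rid in rs.provenance:
                rec = rs.provenance[rid]
                rs.provenance[rid] = ProvenanceRecord(
                    rec.substrate, rec.start, rec.end, rec.strand, 0, region.name
                )
            tmp = ReadSet(reads, prov)
            tmp.extend(rs)
    if n_bg > 0:
        weights = np.array([g.baseline_expression * g.length for g in genes], float)
        if weights.sum() <= 0:
            raise ValueError("no expressed transcripts for background")
        picks = rng.choice(len(genes), size=n_bg, p=weights / weights.sum())
        lens = rng.choice(BACKGROUND_SIZES, size=n_bg)
        for i in range(n_bg):
            g = genes[picks[i]]
            ln = int(lens[i])
            s = int(rng.integers(g.start, g.end - ln + 1))
            seq = genome[g.chromosome][s : s + ln]
            if g.strand == "-":
                seq = revcomp(seq)
            rid = f"{read_prefix}_bg{i:06d}"
            reads.append((rid, seq, _qual(ln)))
            prov[rid] = ProvenanceRecord(g.chromosome, s, s + ln, g.strand, 0, g.id)
    return ReadSet(reads, prov)
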