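"""Synthetic minigenome: a small multi-locus genome with planted locus
archetypes.

The minigenome emulates the locus classes at which Dicer activity leaves
distinct small-RNA footprints in a host without endogenous RNAi:

* a tandem **sense/antisense pair** — two annotated genes overlapping on
  opposite strands, whose co-transcription yields perfect dsRNA;
* a **convergent readthrough pair** — non-overlapping convergent genes
  whose transcription elongates across a short intergenic gap, forming
  dsRNA over the gap and both 3' ends;
* a gene with **unannotated antisense transcription** — a locus whose
  opposite strand is transcribed at a configurable fraction of the
  sense level without any annotated antisense feature;
* a **multicopy repeat element** — identical copies at several
  positions, producing multi-mapping reads and abundant degradation
  fragments;
* neutral **plain genes** with no antisense signal.

Coordinates are 0-based half-open throughout; conversion to the GFF3
1-based inclusive convention happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .._util import derive_rng, random_sequence

GENE_CLASSES = frozenset(
    {"plain", "antisense_pair_member", "readthrough_member", "hidden_antisense", "repeat"}
)


@dataclass
class GeneModel:
    """One annotated gene on the minigenome.

    ``baseline_expression`` is a relative transcription rate (reads per
    transcript copy); ``hidden_antisense_fraction`` is the transcription
    level of the unannotated opposite strand relative to sense, and must
    be zero except for ``hidden_antisense`` loci.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    gene_class: str = "plain"
    baseline_expression: float = 1.0
    hidden_antisense_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene {self.id}: unknown class {self.gene_class!r}")
        if self.baseline_expression < 0:
            raise ValueError(f"gene {self.id}: negative expression")
        if not 0.0 <= self.hidden_antisense_fraction <= 1.0:
            raise ValueError(f"gene {self.id}: hidden_antisense_fraction outside [0,1]")
        if self.hidden_antisense_fraction > 0 and self.gene_class != "hidden_antisense":
            raise ValueError(
                f"gene {self.id}: hidden_antisense_fraction > 0 requires "
                "class 'hidden_antisense'"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MinigenomeSpec:
    """Chromosome sizes, gene layout and the seed that fixes sequence."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    seed: int = 0

    def validate(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.chromosome not in sizes:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chromosome}")
            if g.end > sizes[g.chromosome]:
                raise ValueError(f"gene {g.id}: extends beyond chromosome end")
            by_chrom.setdefault(g.chromosome, []).append(g)
        # same-strand overlaps between distinct genes are rejected:
        # downstream counting assumes at most one same-strand gene per position
        for genes in by_chrom.values():
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    if a.strand == b.strand and a.start < b.end and b.start < a.end:
                        raise ValueError(
                            f"same-strand overlap between {a.id} and {b.id}"
                        )
        classes = {g.gene_class for g in self.genes}
        required = {
            "antisense_pair_member",
            "readthrough_member",
            "hidden_antisense",
            "repeat",
        }
        missing = required - classes
        if missing:
            raise ValueError(f"missing locus classes: {sorted(missing)}")
        if sum(g.gene_class == "plain" for g in self.genes) < 3:
            raise ValueError("need at least 3 plain genes")


def default_minigenome_spec(seed: int = 0) -> MinigenomeSpec:
    """The default study layout: four chromosomes carrying every archetype.

    The sense/antisense pair overlaps by 500 nt (>50% of either gene);
    the convergent pair leaves a 150-nt intergenic gap; the repeat has
    three identical 400-nt copies at elevated expression.
    """
    genes = [
        GeneModel("PLN1", "chrI", 500, 1300, "+", "plain", 1.0),
        GeneModel("PLN2", "chrI", 1800, 2600, "-", "plain", 1.0),
        GeneModel("PLN3", "chrI", 3100, 3900, "+", "plain", 1.0),
        GeneModel("SEN1", "chrII", 800, 1600, "+", "antisense_pair_member", 2.0),
        GeneModel("ASR1", "chrII", 1100, 1900, "-", "antisense_pair_member", 2.0),
        GeneModel("RTA1", "chrIII", 800, 1600, "+", "readthrough_member", 2.0),
        GeneModel("RTB1", "chrIII", 1750, 2550, "-", "readthrough_member", 2.0),
        GeneModel("HID1", "chrIV", 600, 1500, "+", "hidden_antisense", 2.0, 0.2),
        GeneModel("REP1a", "chrIV", 2500, 2900, "+", "repeat", 5.0),
        GeneModel("REP1b", "chrIV", 3500, 3900, "+", "repeat", 5.0),
        GeneModel("REP1c", "chrIV", 4800, 5200, "+", "repeat", 5.0),
    ]
    chromosomes = [("chrI", 6000), ("chrII", 4000), ("chrIII", 4600), ("chrIV", 6500)]
    return MinigenomeSpec(chromosomes=chromosomes, genes=genes, seed=seed)


def build_minigenome(spec: MinigenomeSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Materialise chromosome sequences for a validated spec.

    Returns ``(sequences, genes)`` where sequences is an ordered mapping
    chromosome name -> nucleotide string. All repeat-class genes share
    the sequence of the first repeat copy, making them true multicopy
    elements. Deterministic for a given spec and seed.
    """
    spec.validate()
    rng = derive_rng(spec.seed, 101)
    seqs = {name: list(random_sequence(rng, size)) for name, size in spec.chromosomes}
    repeats = [g for g in spec.genes if g.gene_class == "repeat"]
    if repeats:
        first = repeats[0]
        unit = seqs[first.chromosome][first.start : first.end]
        for g in repeats[1:]:
            if g.length != first.length:
                raise ValueError("repeat copies must share one length")
            seqs[g.chromosome][g.start : g.end] = unit
    return {name: "".join(chars) for name, chars in seqs.items()}, list(spec.genes)


# expected antisense classification for each planted gene class; used by
# the pipeline's confusion matrix against ground truth
EXPECTED_CLASS = {
    "plain": "none",
    "repeat": "none",
    "antisense_pair_member": "annotated_antisense_pair",
    "readthrough_member": "readthrough_overlap",
    "hidden_antisense": "novel_antisense",
}
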