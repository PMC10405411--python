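"""Locus classification by 21/22-nt sense/antisense sRNA signatures.

Dicer activity at a locus leaves a characteristic footprint: 21- and
22-nt sRNAs on *both* strands in near-symmetric amounts, because every
duplex contributes one guide and one passenger strand. Integrated with
stranded RNA-seq coverage, this classifies each annotated gene as:

* ``annotated_antisense_pair`` — overlaps an annotated opposite-strand
  gene and shows symmetric antisense sRNA;
* ``readthrough_overlap`` — a convergent neighbour within a short gap,
  with antisense coverage extending across the intergenic region
  (transcription elongation past the annotated 3' end);
* ``novel_antisense`` — antisense sRNA plus antisense RNA-seq coverage
  without any annotated antisense feature: an unannotated antisense
  transcript;
* ``none`` — no antisense signal above threshold.

sRNAs are assigned to a locus by 5'-end containment, which avoids
double-counting at overlapping loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import SmallReadAlignment, five_prime_position, ppm
from .synthetic.genome import GeneModel

CLASSES = ("annotated_antisense_pair", "readthrough_overlap", "novel_antisense", "none")


@dataclass(frozen=True)
class LocusStrandCounts:
    """Per-locus stranded sRNA (ppm) and RNA-seq (reads/nt) signal."""

    locus_id: str
    sense_srna: float
    antisense_srna: float
    sense_rna: float
    antisense_rna: float
    annotated_antisense_overlap: bool
    downstream_convergent_gene_within: int | None
    intergenic_antisense_fraction: float

    def __post_init__(self) -> None:
        for name in ("sense_srna", "antisense_srna", "sense_rna", "antisense_rna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AntisenseCall:
    locus_id: str
    locus_class: str
    symmetry: float
    evidence: str


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds; all configurable knobs, not reconstructions
    of published cutoffs (none were stated)."""

    min_ppm: float = 5.0
    min_symmetry: float = 0.2
    min_antisense_rna: float = 0.1
    max_gap: int = 300
    min_intergenic_cover: float = 0.5

    def __post_init__(self) -> None:
        if self.min_ppm < 0 or self.min_antisense_rna < 0 or self.max_gap < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_symmetry <= 1.0:
            raise ValueError("min_symmetry outside [0,1]")
        if not 0.0 <= self.min_intergenic_cover <= 1.0:
            raise ValueError("min_intergenic_cover outside [0,1]")


def symmetry_score(sense: float, antisense: float) -> float:
    """2*min(s,a)/(s+a): 1 for perfectly symmetric, 0 for one-sided."""
    if sense < 0 or antisense < 0:
        raise ValueError("counts must be >= 0")
    total = sense + antisense
    if total == 0:
        raise ValueError("symmetry undefined when both counts are zero")
    return 2.0 * min(sense, antisense) / total


def _convergent_partner(gene: GeneModel, genes: list[GeneModel]) -> tuple[int, GeneModel] | None:
    """Nearest downstream convergent gene and the intergenic gap (nt)."""
    best: tuple[int, GeneModel] | None = None
    for other in genes:
        if other.id == gene.id or other.chromosome != gene.chromosome:
            continue
        if other.strand == gene.strand:
            continue
        if gene.strand == "+":
            if other.start >= gene.end:
                gap = other.start - gene.end
            else:
                continue
        else:
            if other.end <= gene.start:
                gap = gene.start - other.end
            else:
                continue
        if best is None or gap < best[0]:
            best = (gap, other)
    return best


def locus_strand_counts(
    alignments: list[SmallReadAlignment],
    genes: list[GeneModel],
    coverage: dict[str, tuple[np.ndarray, np.ndarray]],
    library_size: int,
    sizes: tuple[int, ...] = (21, 22),
    loci: list[str] | None = None,
) -> list[LocusStrandCounts]:
    """Tally stranded 21/22-nt sRNA ppm and RNA coverage per locus.

    sRNA counts are restricted to reads of the given sizes whose 5' end
    lies within the locus; sense/antisense is relative to the annotated
    gene strand. ``coverage`` maps chromosome -> (plus, minus) arrays of
    stranded RNA-seq read coverage.
    """
    by_id = {g.id: g for g in genes}
    if loci is None:
        targets = genes
    else:
        unknown = [l for l in loci if l not in by_id]
        if unknown:
            raise ValueError(f"loci absent from annotation: {unknown}")
        targets = [by_id[l] for l in loci]

    # bin relevant alignments by chromosome once
    rel: dict[str, list[SmallReadAlignment]] = {}
    for a in alignments:
        if a.length in sizes:
            rel.setdefault(a.reference, []).append(a)

    out = []
    for g in targets:
        sense_w = 0.0
        anti_w = 0.0
        for a in rel.get(g.chromosome, []):
            p5 = five_prime_position(a)
            if g.start <= p5 < g.end:
                if a.strand == g.strand:
                    sense_w += a.weight
                else:
                    anti_w += a.weight
        plus_cov, minus_cov = coverage.get(
            g.chromosome, (np.zeros(g.end), np.zeros(g.end))
        )
        sense_cov, anti_cov = (
            (plus_cov, minus_cov) if g.strand == "+" else (minus_cov, plus_cov)
        )
        partner = _convergent_partner(g, genes)
        gap_dist: int | None = None
        intergenic_frac = 0.0
        if partner is not None:
            gap_dist, other = partner
            if g.strand == "+":
                gap_lo, gap_hi = g.end, other.start
            else:
                gap_lo, gap_hi = other.end, g.start
            if gap_hi > gap_lo:
                window = anti_cov[gap_lo:gap_hi]
                intergenic_frac = float((window > 0).mean())
            else:
                intergenic_frac = 1.0  # abutting genes: nothing to cross
        overlap = any(
            o.id != g.id
            and o.chromosome == g.chromosome
            and o.strand != g.strand
            and o.start < g.end
            and g.start < o.end
            for o in genes
        )
        out.append(
            LocusStrandCounts(
                locus_id=g.id,
                sense_srna=ppm(sense_w, library_size),
                antisense_srna=ppm(anti_w, library_size),
                sense_rna=float(sense_cov[g.start : g.end].mean()),
                antisense_rna=float(anti_cov[g.start : g.end].mean()),
                annotated_antisense_overlap=overlap,
                downstream_convergent_gene_within=gap_dist,
                intergenic_antisense_fraction=intergenic_frac,
            )
        )
    return out


def classify_locus(counts: LocusStrandCounts, thresholds: Thresholds) -> AntisenseCall:
    """Decision cascade over the antisense evidence at one locus."""
    if not isinstance(thresholds, Thresholds):
        raise TypeError("thresholds must be a Thresholds instance")
    s, a = counts.sense_srna, counts.antisense_srna
    sym = symmetry_score(s, a) if s + a > 0 else 0.0
    if a >= thresholds.min_ppm:
        if counts.annotated_antisense_overlap and sym >= thresholds.min_symmetry:
            return AntisenseCall(
                counts.locus_id,
                "annotated_antisense_pair",
                sym,
                f"antisense {a:.1f} ppm, symmetry {sym:.2f}, annotated overlap",
            )
        if (
            counts.downstream_convergent_gene_within is not None
            and counts.downstream_convergent_gene_within <= thresholds.max_gap
            and counts.intergenic_antisense_fraction >= thresholds.min_intergenic_cover
        ):
            return AntisenseCall(
                counts.locus_id,
                "readthrough_overlap",
                sym,
                f"antisense {a:.1f} ppm, convergent gene at "
                f"{counts.downstream_convergent_gene_within} nt, intergenic antisense "
                f"coverage {counts.intergenic_antisense_fraction:.0%}",
            )
        if counts.antisense_rna >= thresholds.min_antisense_rna:
            return AntisenseCall(
                counts.locus_id,
                "novel_antisense",
                sym,
                f"antisense {a:.1f} ppm with {counts.antisense_rna:.2f} reads/nt "
                "antisense coverage, no annotated antisense feature",
            )
    return AntisenseCall(counts.locus_id, "none", sym, "no antisense signal above threshold")


def call_genome(
    alignments: list[SmallReadAlignment],
    genes: list[GeneModel],
    coverage: dict[str, tuple[np.ndarray, np.ndarray]],
    library_size: int,
    thresholds: Thresholds | None = None,
    sizes: tuple[int, ...] = (21, 22),
) -> tuple[list[AntisenseCall], list[LocusStrandCounts]]:
    """One antisense call per annotated locus."""
    thresholds = thresholds or Thresholds()
    counts = locus_strand_counts(alignments, genes, coverage, library_size, sizes)
    calls = [classify_locus(c, thresholds) for c in counts]
    return calls, counts


def write_bed(
    calls: list[AntisenseCall], genes: list[GeneModel], path
) -> None:
    """BED6: class in the name field, symmetry scaled to [0,1000]."""
    by_id = {g.id: g for g in genes}
    with open(path, "w") as fh:
        for call in calls:
            g = by_id[call.locus_id]
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        f"{call.locus_id}|{call.locus_class}",
                        str(int(round(call.symmetry * 1000))),
                        g.strand,
                    ]
                )
                + "\n"
            )
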