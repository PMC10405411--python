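"""Stranded RNA-seq read simulation over the minigenome annotation.

Reads are allocated to genes by a multinomial with weights proportional
to ``baseline_expression x length``; positions are uniform within the
transcript. Two locus classes emit opposite-strand signal:

* ``hidden_antisense`` genes emit an antisense-strand read with
  probability ``hidden_antisense_fraction`` — an unannotated antisense
  transcript covering the gene body;
* ``readthrough_member`` genes extend a fraction of their transcripts
  past the annotated 3' end, across the intergenic gap and into the
  convergent neighbour.
"""

from __future__ import annotations

import numpy as np

from .._util import derive_rng, revcomp
from .dicer import ProvenanceRecord, ReadSet
from .genome import GeneModel


def simulate_rnaseq(
    genome: dict[str, str],
    genes: list[GeneModel],
    n_reads: int,
    read_length: int = 50,
    stranded: bool = True,
    expression: dict[str, float] | None = None,
    seed: int = 0,
    readthrough_extension: int = 300,
    readthrough_fraction: float = 0.3,
    read_prefix: str = "rna",
) -> ReadSet:
    """Simulate an RNA-seq library.

    ``expression`` overrides per-gene baseline expression (gene id ->
    relative level); referencing an unknown gene is an error. When
    ``stranded`` is false the sequenced orientation of each read is
    randomised, as in an unstranded protocol.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = derive_rng(seed, 107)
    by_id = {g.id: g for g in genes}
    expr = {g.id: g.baseline_expression for g in genes}
    if expression is not None:
        unknown = set(expression) - set(by_id)
        if unknown:
            raise ValueError(f"expression profile references unknown genes: {sorted(unknown)}")
        expr.update(expression)

    reads: list[tuple[str, str, str]] = []
    prov: dict[str, ProvenanceRecord] = {}
    if n_reads == 0:
        return ReadSet(reads, prov)

    weights = np.array([expr[g.id] * g.length for g in genes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no expressed genes")
    counts = rng.multinomial(n_reads, weights / weights.sum())

    idx = 0
    for g, n_g in zip(genes, counts):
        if n_g == 0:
            continue
        chrom_seq = genome[g.chromosome]
        chrom_len = len(chrom_seq)
        lo, hi = g.start, g.end  # transcript span used for position draws
        if g.gene_class == "readthrough_member":
            readthrough = rng.random(n_g) < readthrough_fraction
        else:
            readthrough = np.zeros(n_g, dtype=bool)
        if g.gene_class == "hidden_antisense":
            antisense = rng.random(n_g) < g.hidden_antisense_fraction
        else:
            antisense = np.zeros(n_g, dtype=bool)
        for j in range(n_g):
            span_lo, span_hi = lo, hi
            if readthrough[j]:
                if g.strand == "+":
                    span_hi = min(hi + readthrough_extension, chrom_len)
                else:
                    span_lo = max(lo - readthrough_extension, 0)
            s_lo = span_lo
            s_hi = max(span_lo, span_hi - read_length)
            s = int(rng.integers(s_lo, s_hi + 1))
            e = min(s + read_length, chrom_len)
            strand = g.strand
            if antisense[j]:
                strand = "-" if strand == "+" else "+"
            seq = chrom_seq[s:e]
            if strand == "-":
                seq = revcomp(seq)
            if not stranded and rng.random() < 0.5:
                seq = revcomp(seq)
                strand = "-" if strand == "+" else "+"
            rid = f"{read_prefix}_{idx:07d}"
            idx += 1
            reads.append((rid, seq, "I" * len(seq)))
            prov[rid] = ProvenanceRecord(g.chromosome, s, e, strand, 0, g.id)
    return ReadSet(reads, prov)
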