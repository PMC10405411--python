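"""File I/O for the synthetic data: FASTA references, GFF3 annotation,
FASTQ reads and the tab-separated provenance (ground-truth) table.

Internal coordinates are 0-based half-open; GFF3 is written and read in
its native 1-based inclusive convention.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dicer import ProvenanceRecord, ReadSet
from .genome import GeneModel


def write_reference(sequences: dict[str, str], path: str | Path) -> None:
    """Write reference sequences as FASTA (sorted by insertion order)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads(readset: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as FASTQ (4 lines per read, constant quality)."""
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_annotation(genes: list[GeneModel], path: str | Path, source: str = "dicerscope") -> None:
    """Write gene models as GFF3, converting to 1-based inclusive coords."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.id};gene_class={g.gene_class};"
                f"baseline_expression={g.baseline_expression:g};"
                f"hidden_antisense_fraction={g.hidden_antisense_fraction:g}"
            )
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        source,
                        "gene",
                        str(g.start + 1),  # 1-based inclusive start
                        str(g.end),  # half-open end == inclusive end
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models back from GFF3 (via gffutils)."""
    import gffutils

    with tempfile.TemporaryDirectory() as tmp:
        db = gffutils.create_db(
            str(path),
            dbfn=os.path.join(tmp, "ann.db"),
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        genes = []
        for feat in db.all_features(order_by=("seqid", "start")):
            genes.append(
                GeneModel(
                    id=feat.attributes["ID"][0],
                    chromosome=feat.seqid,
                    start=feat.start - 1,  # back to 0-based half-open
                    end=feat.end,
                    strand=feat.strand,
                    gene_class=feat.attributes.get("gene_class", ["plain"])[0],
                    baseline_expression=float(
                        feat.attributes.get("baseline_expression", ["1"])[0]
                    ),
                    hidden_antisense_fraction=float(
                        feat.attributes.get("hidden_antisense_fraction", ["0"])[0]
                    ),
                )
            )
    return genes


PROVENANCE_COLUMNS = ["read_id", "substrate", "start", "end", "strand", "n_mutations", "source"]


def write_provenance(readset: ReadSet, path: str | Path) -> None:
    rows = [
        (rid, rec.substrate, rec.start, rec.end, rec.strand, rec.n_mutations, rec.source)
        for rid, rec in readset.provenance.items()
    ]
    pd.DataFrame(rows, columns=PROVENANCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_provenance(path: str | Path) -> dict[str, ProvenanceRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    return {
        row.read_id: ProvenanceRecord(
            row.substrate, int(row.start), int(row.end), row.strand,
            int(row.n_mutations), row.source,
        )
        for row in df.itertuples()
    }
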