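"""End-to-end orchestration: simulate -> align -> hairpin -> antisense
-> differential expression, with one seed and one report.

Every stage writes its standard text outputs (FASTA/GFF3/FASTQ/TSV/BED)
under the configured output directory, and the report summarises
numbers that are all recomputable from those files. Identical config
and seed produce a byte-identical report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import antisense as asmod
from . import diffexpr as demod
from . import hairpin_analysis as hpmod
from .align import (
    ReferenceIndex,
    align_reads,
    coverage_from_alignments,
    count_unique_sequences,
    five_prime_profile,
    ppm,
    size_distribution,
    write_alignments,
)
from .synthetic import (
    DicerModel,
    ReadSet,
    build_hairpin,
    build_minigenome,
    build_replicon,
    default_minigenome_spec,
    simulate_dicer_products,
    simulate_genome_srna,
    simulate_replicon_reads,
    simulate_rnaseq,
    write_annotation,
    write_provenance,
    write_reads,
    write_reference,
)
from .synthetic.genome import EXPECTED_CLASS


@dataclass
class RunConfig:
    """All knobs of one pipeline run; everything funnels through ``seed``."""

    seed: int = 1
    outdir: str = "dicerscope_run"
    # minigenome
    minigenome_seed_offset: int = 0
    # hairpin construct
    arm_length: int = 275
    loop_length: int = 79
    hairpin_background_fraction: float = 0.3
    # replicon
    replicon_length: int = 477
    replicon_mutation_rate: float = 0.03
    replicon_accessibility: float = 0.01
    # Dicer model
    size_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.1, 21: 0.6, 22: 0.3}
    )
    loop_leak: float = 0.0
    strand_emission: float = 0.5
    genome_background_fraction: float = 0.1
    # depths
    n_srna_genome: int = 100_000
    n_srna_hairpin: int = 30_000
    n_replicon_molecules: int = 20_000
    n_rnaseq: int = 200_000
    rnaseq_read_length: int = 50
    # analysis
    max_mismatch: int = 1
    boundary_window: int = 20
    thresholds: asmod.Thresholds = field(default_factory=asmod.Thresholds)
    # differential expression: per-replicate depth and induced fold changes
    n_de_replicates: int = 3
    n_de_reads: int = 30_000
    induced_fold_changes: dict[str, float] = field(
        default_factory=lambda: {"REP1a": 0.5, "REP1b": 0.5, "REP1c": 0.5, "HID1": 0.35}
    )

    def validate(self) -> None:
        DicerModel(dict(self.size_weights), 2, self.loop_leak, self.strand_emission, 0.0)
        if min(self.n_srna_genome, self.n_srna_hairpin, self.n_replicon_molecules) < 0:
            raise ValueError("depths must be >= 0")
        if self.n_rnaseq < 0 or self.n_de_reads < 0:
            raise ValueError("depths must be >= 0")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.arm_length < 0 or self.loop_length < 1:
            raise ValueError("invalid hairpin geometry")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "thresholds" in data and isinstance(data["thresholds"], dict):
        data["thresholds"] = asmod.Thresholds(**data["thresholds"])
    if "size_weights" in data:
        data["size_weights"] = {int(k): float(v) for k, v in data["size_weights"].items()}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineReport:
    """Summary numbers plus the text rendering written to disk."""

    total_srna_reads: int
    mapped_srna_weight: float
    size_histogram: dict[int, float]
    hairpin_fraction_total: float
    hairpin_fraction_mapped: float
    boundary_calls: dict[str, tuple[int, float]]
    antisense_calls: dict[str, str]
    confusion: pd.DataFrame
    classification_accuracy: float
    replicon_ppm: float
    hairpin_ppm: float
    replicon_unique_plus: int
    replicon_unique_minus: int
    n_significant: int
    n_up: int
    n_down: int
    text: str


def _confusion(expected: dict[str, str], observed: dict[str, str]) -> pd.DataFrame:
    classes = list(asmod.CLASSES)
    mat = pd.DataFrame(0, index=classes, columns=classes)
    for locus, exp in expected.items():
        mat.loc[exp, observed[locus]] += 1
    mat.index.name = "expected"
    mat.columns.name = "observed"
    return mat


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute every stage; see the module docstring."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- simulate ---------------------------------------------------
        stage = "simulate"
        spec = default_minigenome_spec(seed=config.seed + config.minigenome_seed_offset)
        genome, genes = build_minigenome(spec)
        hairpin = build_hairpin(config.arm_length, config.loop_length, seed=config.seed)
        replicon = build_replicon(
            config.replicon_length,
            config.replicon_mutation_rate,
            config.replicon_accessibility,
            seed=config.seed,
        )
        dicer_genome = DicerModel(
            dict(config.size_weights),
            2,
            0.0,
            config.strand_emission,
            config.genome_background_fraction,
        )
        dicer_hairpin = DicerModel(
            dict(config.size_weights),
            2,
            config.loop_leak,
            config.strand_emission,
            config.hairpin_background_fraction,
        )
        transcript_pool = [
            (g.chromosome, genome[g.chromosome][g.start : g.end]) for g in genes
        ]
        srna = simulate_genome_srna(
            genome, genes, dicer_genome, config.n_srna_genome, seed=config.seed
        )
        hp_yield = simulate_dicer_products(
            hairpin,
            dicer_hairpin,
            config.n_srna_hairpin,
            seed=config.seed + 1,
            background_pool=transcript_pool,
            read_prefix="hp",
        )
        # hairpin background reads come from genome transcripts; relabel ids
        # are already unique via prefixes
        di = simulate_replicon_reads(
            replicon,
            DicerModel(dict(config.size_weights), 2, 0.0, config.strand_emission, 0.0),
            config.n_replicon_molecules,
            seed=config.seed + 2,
        )
        library = ReadSet([], {})
        library.extend(srna)
        library.extend(hp_yield.reads)
        library.extend(di)

        references = dict(genome)
        references["hairpin"] = hairpin.transcript_sequence
        references["replicon"] = replicon.sequence

        write_reference(references, outdir / "reference.fasta")
        write_annotation(genes, outdir / "annotation.gff3")
        write_reads(library, outdir / "srna_reads.fastq")
        write_provenance(library, outdir / "srna_provenance.tsv")

        # --- align ------------------------------------------------------
        stage = "align"
        index = ReferenceIndex(references)
        reads = [(rid, seq) for rid, seq, _ in library.reads]
        alignments = align_reads(reads, index, max_mismatch=config.max_mismatch)
        write_alignments(alignments, outdir / "srna_alignments.tsv")
        library_size = len(library)
        # empty libraries keep the report well-defined (all-zero summaries)
        ppm_denom = library_size if library_size > 0 else 1
        mapped_weight = sum(a.weight for a in alignments)
        hist = size_distribution(alignments, (17, 24), library_size=ppm_denom)
        pd.Series(hist.counts).rename_axis("length").rename("weight").to_csv(
            outdir / "size_histogram.tsv", sep="\t"
        )

        # --- hairpin analysis --------------------------------------------
        stage = "hairpin"
        partition = hpmod.StemLoopPartition.from_construct(hairpin)
        hp_alignments = [a for a in alignments if a.reference == "hairpin"]
        frac = hpmod.hairpin_fraction(alignments, partition, ppm_denom)
        profile = five_prime_profile(hp_alignments, "hairpin", hairpin.length)
        if profile.total > 0:
            boundary = hpmod.scan_boundary(profile, partition, config.boundary_window)
            boundary_calls = {
                d: (c.boundary_position, c.p_adjusted) for d, c in boundary.items()
            }
        else:
            boundary_calls = {}
        sizes_prof = hpmod.per_size_profiles(hp_alignments, "hairpin", hairpin.length)
        rows = []
        for k, prof in sorted(sizes_prof.items()):
            for pos in range(hairpin.length):
                if prof.plus[pos] or prof.minus[pos]:
                    rows.append((k, pos, prof.plus[pos], prof.minus[pos]))
        pd.DataFrame(rows, columns=["size", "pos0", "plus", "minus"]).to_csv(
            outdir / "hairpin_profiles.tsv", sep="\t", index=False
        )

        # --- replicon summary ---------------------------------------------
        stage = "replicon"
        di_ids = {rid for rid, _, _ in di.reads}
        hp_duplex_ids = {
            rid
            for rid, rec in hp_yield.reads.provenance.items()
            if rec.source == "duplex"
        }
        repl_w = sum(a.weight for a in alignments if a.read_id in di_ids)
        hp_w = sum(a.weight for a in alignments if a.read_id in hp_duplex_ids)
        seqs = library.sequences()
        repl_alns = [a for a in alignments if a.reference == "replicon"]
        uniq_plus = count_unique_sequences(repl_alns, seqs, "replicon", "+")
        uniq_minus = count_unique_sequences(repl_alns, seqs, "replicon", "-")

        # --- antisense --------------------------------------------------
        stage = "antisense"
        rnaseq = simulate_rnaseq(
            genome,
            genes,
            config.n_rnaseq,
            read_length=config.rnaseq_read_length,
            seed=config.seed + 3,
        )
        rna_aln = align_reads(
            [(rid, s) for rid, s, _ in rnaseq.reads], index, max_mismatch=0
        )
        coverage = coverage_from_alignments(
            rna_aln, {name: len(seq) for name, seq in genome.items()}
        )
        cov_rows = []
        for name in genome:
            plus, minus = coverage[name]
            for pos in np.flatnonzero((plus > 0) | (minus > 0)):
                cov_rows.append((name, int(pos), plus[pos], minus[pos]))
        pd.DataFrame(
            cov_rows, columns=["reference", "pos0", "plus", "minus"]
        ).to_csv(outdir / "rnaseq_coverage.tsv", sep="\t", index=False)
        calls, counts = asmod.call_genome(
            alignments, genes, coverage, ppm_denom, config.thresholds
        )
        asmod.write_bed(calls, genes, outdir / "antisense_calls.bed")
        pd.DataFrame(
            [(c.locus_id, c.locus_class, c.symmetry, c.evidence) for c in calls],
            columns=["locus", "class", "symmetry", "evidence"],
        ).to_csv(outdir / "antisense_calls.tsv", sep="\t", index=False)
        expected = {g.id: EXPECTED_CLASS[g.gene_class] for g in genes}
        observed = {c.locus_id: c.locus_class for c in calls}
        confusion = _confusion(expected, observed)
        accuracy = float(
            np.mean([observed[g] == e for g, e in expected.items()])
        )

        # --- differential expression --------------------------------------
        stage = "diffexpr"
        cols = {}
        labels = []
        for cond, fold in (("control", None), ("induced", config.induced_fold_changes)):
            for rep in range(config.n_de_replicates):
                expr = None
                if fold:
                    expr = {
                        g.id: g.baseline_expression * fold.get(g.id, 1.0) for g in genes
                    }
                rs = simulate_rnaseq(
                    genome,
                    genes,
                    config.n_de_reads,
                    read_length=config.rnaseq_read_length,
                    expression=expr,
                    seed=config.seed + 10 + len(labels),
                    read_prefix=f"de_{cond}{rep}",
                )
                aln = align_reads([(rid, s) for rid, s, _ in rs.reads], index, 0)
                per_read: dict[str, list] = {}
                for a in aln:
                    per_read.setdefault(a.read_id, []).append(a)
                cols[f"{cond}_{rep}"] = demod.count_genes(per_read, genes)
                labels.append(cond)
        matrix = pd.DataFrame(cols)
        matrix.to_csv(outdir / "de_counts.tsv", sep="\t")
        de_results = demod.nb_wald_test(matrix, labels, reference="control")
        demod.results_frame(de_results).to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        sig = demod.filter_significant(de_results)
        n_up = sum(r.log2FC > 0 for r in sig)
        n_down = sum(r.log2FC < 0 for r in sig)
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = PipelineReport(
        total_srna_reads=library_size,
        mapped_srna_weight=mapped_weight,
        size_histogram=hist.counts,
        hairpin_fraction_total=frac.of_total,
        hairpin_fraction_mapped=frac.of_mapped,
        boundary_calls=boundary_calls,
        antisense_calls=observed,
        confusion=confusion,
        classification_accuracy=accuracy,
        replicon_ppm=ppm(repl_w, ppm_denom),
        hairpin_ppm=ppm(hp_w, ppm_denom),
        replicon_unique_plus=uniq_plus,
        replicon_unique_minus=uniq_minus,
        n_significant=len(sig),
        n_up=n_up,
        n_down=n_down,
        text="",
    )
    report.text = render_report(report, config)
    (outdir / "report.md").write_text(report.text)
    return report


def render_report(report: PipelineReport, config: RunConfig) -> str:
    lines = [
        "# dicerscope run report",
        "",
        f"seed: {config.seed}",
        "",
        "## Library",
        f"- total sRNA reads: {report.total_srna_reads}",
        f"- mapped weight: {report.mapped_srna_weight:.1f}",
        "",
        "## sRNA size histogram (weighted counts)",
    ]
    for k in sorted(report.size_histogram):
        lines.append(f"- {k} nt: {report.size_histogram[k]:.1f}")
    lines += [
        "",
        "## Hairpin processing",
        f"- stem-derived fraction of total reads: {report.hairpin_fraction_total:.4f}",
        f"- stem-derived fraction of mapped reads: {report.hairpin_fraction_mapped:.4f}",
    ]
    for direction, (pos, padj) in sorted(report.boundary_calls.items()):
        lines.append(f"- boundary {direction}: position {pos}, adjusted p {padj:.3g}")
    lines += [
        "",
        "## Replicon protection",
        f"- replicon-derived sRNA: {report.replicon_ppm:.1f} ppm",
        f"- hairpin duplex-derived sRNA: {report.hairpin_ppm:.1f} ppm",
        f"- unique replicon sRNAs: {report.replicon_unique_plus} (+) / "
        f"{report.replicon_unique_minus} (-)",
        "",
        "## Antisense classification",
        f"- accuracy vs planted truth: {report.classification_accuracy:.3f}",
        "",
        report.confusion.to_string(),
        "",
        "## Differential expression",
        f"- significant genes: {report.n_significant} "
        f"({report.n_up} up, {report.n_down} down)",
        "",
    ]
    return "\n".join(lines)
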