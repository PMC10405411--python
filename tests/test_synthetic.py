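"""Generator-level tests: minigenome construction, hairpin geometry,
Dicer duplex statistics, replicon mutation, RNA-seq allocation, file
round-trips."""

import numpy as np
import pytest

from dicerscope._util import revcomp
from dicerscope.synthetic import (
    DicerModel,
    GeneModel,
    MinigenomeSpec,
    RepliconModel,
    build_hairpin,
    build_minigenome,
    build_replicon,
    default_minigenome_spec,
    read_annotation,
    read_reference,
    simulate_dicer_products,
    simulate_genome_srna,
    simulate_replicon_reads,
    simulate_rnaseq,
    write_annotation,
    write_reads,
    write_reference,
)
from dicerscope.synthetic.dicer import ReadSet


class TestMinigenome:
    def test_reciprocal_antisense_overlap(self, minigenome):
        _, genes = minigenome
        pair = [g for g in genes if g.gene_class == "antisense_pair_member"]
        assert len(pair) == 2
        a, b = pair
        overlap = min(a.end, b.end) - max(a.start, b.start)
        assert a.strand != b.strand
        assert overlap >= 0.5 * min(a.length, b.length)

    def test_convergent_gap_within_200(self, minigenome):
        _, genes = minigenome
        rt = sorted(
            (g for g in genes if g.gene_class == "readthrough_member"),
            key=lambda g: g.start,
        )
        plus, minus = rt
        assert (plus.strand, minus.strand) == ("+", "-")
        assert 0 < minus.start - plus.end <= 200

    def test_deterministic_for_seed(self, tmp_path):
        spec = default_minigenome_spec(seed=1)
        for sub in ("a", "b"):
            genome, genes = build_minigenome(spec)
            d = tmp_path / sub
            d.mkdir()
            write_reference(genome, d / "ref.fasta")
            write_annotation(genes, d / "ann.gff3")
        assert (tmp_path / "a/ref.fasta").read_bytes() == (tmp_path / "b/ref.fasta").read_bytes()
        assert (tmp_path / "a/ann.gff3").read_bytes() == (tmp_path / "b/ann.gff3").read_bytes()

    def test_repeat_copies_share_sequence(self, minigenome):
        genome, genes = minigenome
        reps = [g for g in genes if g.gene_class == "repeat"]
        units = {genome[g.chromosome][g.start : g.end] for g in reps}
        assert len(reps) >= 2 and len(units) == 1

    def test_gene_beyond_chromosome_rejected(self):
        spec = default_minigenome_spec(seed=0)
        spec.genes.append(GeneModel("BAD", "chrI", 5500, 6500, "+"))
        with pytest.raises(ValueError, match="beyond"):
            build_minigenome(spec)

    def test_same_strand_overlap_rejected(self):
        spec = default_minigenome_spec(seed=0)
        spec.genes.append(GeneModel("BAD", "chrI", 600, 900, "+"))
        with pytest.raises(ValueError, match="overlap"):
            build_minigenome(spec)

    def test_missing_archetype_rejected(self):
        spec = MinigenomeSpec(
            chromosomes=[("chrI", 1000)],
            genes=[GeneModel(f"G{i}", "chrI", i * 200, i * 200 + 100, "+") for i in range(3)],
        )
        with pytest.raises(ValueError, match="missing locus classes"):
            spec.validate()


class TestHairpinConstruct:
    def test_default_geometry_629(self):
        hp = build_hairpin(275, 79, seed=0)
        assert hp.length == 629
        assert hp.stem_intervals == ((0, 275), (354, 629))
        assert hp.loop_interval == (275, 354)

    def test_second_arm_is_reverse_complement(self, hairpin275):
        t = hairpin275.transcript_sequence
        assert t[354:629] == revcomp(t[0:275])

    def test_degenerate_armless(self):
        hp = build_hairpin(0, 50, seed=0)
        assert hp.length == 50
        assert hp.stem_intervals == ((0, 0), (50, 50))

    @pytest.mark.parametrize("arm,loop", [(-1, 10), (10, 0)])
    def test_invalid_lengths_rejected(self, arm, loop):
        with pytest.raises(ValueError):
            build_hairpin(arm, loop)

    def test_small_interval_arithmetic(self):
        hp = build_hairpin(10, 4, seed=0)
        assert hp.stem_intervals == ((0, 10), (14, 24))
        assert hp.loop_interval == (10, 14)


class TestDicerProducts:
    def test_duplex_geometry_two_nt_overhangs(self, hairpin_yield):
        for d in hairpin_yield.duplexes:
            (ps, pe), (ms, me) = d.plus_interval, d.minus_interval
            assert pe - ps == me - ms == d.size
            assert ps - ms == 2 and pe - me == 2

    def test_size_weight_recovery_within_3se(self, hairpin_yield):
        sizes = [d.size for d in hairpin_yield.duplexes]
        n = len(sizes)
        for k, w in {20: 0.1, 21: 0.6, 22: 0.3}.items():
            obs = sizes.count(k) / n
            se = np.sqrt(w * (1 - w) / n)
            assert abs(obs - w) <= 3 * se

    def test_loop_exclusion_exhaustive(self, hairpin275, hairpin_yield):
        lo, hi = hairpin275.loop_interval
        for d in hairpin_yield.duplexes:
            for s, e in (d.plus_interval, d.minus_interval):
                assert e <= lo or s >= hi
        for rec in hairpin_yield.reads.provenance.values():
            assert rec.end <= lo or rec.start >= hi

    def test_zero_products(self, hairpin275):
        y = simulate_dicer_products(
            hairpin275, DicerModel(background_fraction=0.0), 0, seed=1
        )
        assert y.duplexes == [] and len(y.reads) == 0

    def test_no_ds_region_errors(self):
        hp = build_hairpin(10, 40, seed=0)  # arms shorter than a product
        with pytest.raises(ValueError, match="double-stranded"):
            simulate_dicer_products(hp, DicerModel(background_fraction=0.0), 10, seed=0)

    def test_reads_are_transcript_substrings(self, hairpin275, hairpin_yield):
        t = hairpin275.transcript_sequence
        for rid, seq, _ in hairpin_yield.reads.reads[:500]:
            rec = hairpin_yield.reads.provenance[rid]
            assert seq == t[rec.start : rec.end]

    def test_provenance_covers_every_read(self, hairpin_yield):
        ids = {rid for rid, _, _ in hairpin_yield.reads.reads}
        assert ids == set(hairpin_yield.reads.provenance)

    def test_duplicate_read_ids_rejected(self, hairpin_yield):
        rs = ReadSet(list(hairpin_yield.reads.reads), dict(hairpin_yield.reads.provenance))
        with pytest.raises(ValueError, match="duplicate"):
            rs.extend(hairpin_yield.reads)


class TestReplicon:
    def test_defaults_match_scenario(self):
        r = build_replicon(seed=3)
        assert r.length == 477
        assert r.per_site_mutation_rate == 0.03
        assert r.accessibility < 0.1

    def test_no_mutation_reads_are_substrings(self):
        r = RepliconModel(build_replicon(seed=3).sequence, 0.0, 1.0)
        rs = simulate_replicon_reads(r, DicerModel(background_fraction=0.0), 500, seed=2)
        assert len(rs) == 500
        for rid, seq, _ in rs.reads:
            assert seq in r.sequence or revcomp(seq) in r.sequence

    def test_mismatch_fraction_matches_closed_form(self):
        # P(read of 21 nt carries >=1 variant) = 1 - 0.97^21 ~ 0.473
        r = RepliconModel(build_replicon(seed=3).sequence, 0.03, 1.0)
        dicer = DicerModel(size_weights={21: 1.0}, background_fraction=0.0)
        rs = simulate_replicon_reads(r, dicer, 8000, seed=4)
        frac = np.mean([rec.n_mutations >= 1 for rec in rs.provenance.values()])
        expected = 1 - 0.97**21
        se = np.sqrt(expected * (1 - expected) / len(rs))
        assert abs(frac - expected) <= 3 * se

    def test_inaccessible_replicon_silent(self):
        r = RepliconModel(build_replicon(seed=3).sequence, 0.03, 0.0)
        rs = simulate_replicon_reads(r, DicerModel(), 5000, seed=5)
        assert len(rs) == 0


class TestRnaseq:
    def test_expression_ratio_recovered(self, minigenome):
        genome, genes = minigenome
        expr = {g.id: 0.0 for g in genes}
        expr.update({"PLN1": 3.0, "PLN3": 1.0})  # equal 800-nt genes
        rs = simulate_rnaseq(genome, genes, 40_000, expression=expr, seed=11)
        src = [rec.source for rec in rs.provenance.values()]
        n1, n3 = src.count("PLN1"), src.count("PLN3")
        p = 0.75
        se = np.sqrt(p * (1 - p) / 40_000)
        assert abs(n1 / (n1 + n3) - p) <= 3 * se

    def test_hidden_antisense_fraction(self, minigenome):
        genome, genes = minigenome
        expr = {g.id: 0.0 for g in genes}
        expr["HID1"] = 1.0
        rs = simulate_rnaseq(genome, genes, 20_000, expression=expr, seed=12)
        hid = next(g for g in genes if g.id == "HID1")
        anti = np.mean(
            [rec.strand != hid.strand for rec in rs.provenance.values()]
        )
        se = np.sqrt(0.2 * 0.8 / 20_000)
        assert abs(anti - 0.2) <= 3 * se

    def test_empty_library(self, minigenome):
        genome, genes = minigenome
        assert len(simulate_rnaseq(genome, genes, 0, seed=1)) == 0

    def test_unknown_gene_rejected(self, minigenome):
        genome, genes = minigenome
        with pytest.raises(ValueError, match="unknown genes"):
            simulate_rnaseq(genome, genes, 10, expression={"NOPE": 1.0}, seed=1)


class TestGenomeSrna:
    def test_planted_antisense_loci_have_antisense_reads(self, minigenome):
        genome, genes = minigenome
        rs = simulate_genome_srna(genome, genes, DicerModel(), 20_000, seed=13)
        sources = {rec.source for rec in rs.provenance.values()}
        assert any(s.startswith("as:") for s in sources)
        assert any(s.startswith("rt:") for s in sources)
        assert any(s.startswith("ha:") for s in sources)

    def test_background_reads_on_transcript_strand(self, minigenome):
        genome, genes = minigenome
        rs = simulate_genome_srna(genome, genes, DicerModel(), 5_000, seed=14)
        by_id = {g.id: g for g in genes}
        for rec in rs.provenance.values():
            if rec.source in by_id:
                assert rec.strand == by_id[rec.source].strand


class TestIO:
    def test_fastq_has_four_lines_per_read(self, tmp_path, hairpin_yield):
        rs = ReadSet(
            hairpin_yield.reads.reads[:3],
            {
                rid: hairpin_yield.reads.provenance[rid]
                for rid, _, _ in hairpin_yield.reads.reads[:3]
            },
        )
        path = tmp_path / "r.fastq"
        write_reads(rs, path)
        assert len(path.read_text().splitlines()) == 12

    def test_fasta_round_trip(self, tmp_path, minigenome):
        genome, _ = minigenome
        path = tmp_path / "ref.fasta"
        write_reference(genome, path)
        assert read_reference(path) == genome

    def test_gff3_one_based_inclusive(self, tmp_path):
        g = GeneModel("G", "chr", 10, 20, "+")
        path = tmp_path / "a.gff3"
        write_annotation([g], path)
        line = path.read_text().splitlines()[1].split("\t")
        assert (line[3], line[4]) == ("11", "20")

    def test_gff3_round_trip(self, tmp_path, minigenome):
        _, genes = minigenome
        path = tmp_path / "ann.gff3"
        write_annotation(genes, path)
        back = read_annotation(path)
        assert len(back) == len(genes)
        by_id = {g.id: g for g in back}
        for g in genes:
            r = by_id[g.id]
            assert (r.start, r.end, r.strand, r.gene_class) == (
                g.start, g.end, g.strand, g.gene_class
            )

    def test_identical_seed_identical_fastq(self, tmp_path, hairpin275):
        model = DicerModel(background_fraction=0.2)
        for sub in ("a", "b"):
            y = simulate_dicer_products(hairpin275, model, 500, seed=9)
            write_reads(y.reads, tmp_path / f"{sub}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
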