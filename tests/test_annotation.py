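"""Annotation builder: stage semantics and per-base oracle equivalence."""

import subprocess

import numpy as np
import pytest

from inextools.annotation import (
    TranscriptModel,
    build_reference,
    collapse_and_merge,
    compute_length_table,
    derive_introns,
    filter_fully_covered_transcripts,
    filter_protein_coding_exons,
    group_transcripts,
    subtract_ambiguous,
    used_exon_ids,
)
from inextools.gtf_io import GenomicInterval, GtfRecord

from .conftest import exon_record, random_toy_genome
from .oracles import annotation_to_tuples, label_reference, length_table_bruteforce


def _exon(start, end, strand="+", gene="G", tid="T1", eid=None, biotype="protein_coding"):
    return exon_record("chrT", start, end, strand, gene, tid, eid or f"E{start}", biotype)


def _intron(start, end, strand="+", gene="G"):
    return GtfRecord(
        interval=GenomicInterval("chrT", start, end, strand),
        source="calculated",
        feature_type="intron",
        attributes={"gene_id": gene},
    )


class TestProteinCodingFilter:
    def test_keeps_only_protein_coding_exons(self):
        records = [
            _exon(0, 10),
            _exon(20, 30, biotype="lncRNA"),
        ]
        records.append(
            GtfRecord(
                interval=GenomicInterval("chrT", 40, 50, "+"),
                feature_type="intron",
                attributes={"gene_id": "G", "gene_biotype": "protein_coding"},
            )
        )
        kept = list(filter_protein_coding_exons(records))
        assert kept == [records[0]]

    def test_loss_of_function_biotype_kept(self):
        rec = _exon(0, 10, biotype="protein_coding_LoF")
        assert list(filter_protein_coding_exons([rec])) == [rec]

    def test_empty_input(self):
        assert list(filter_protein_coding_exons([])) == []


class TestUsedExons:
    def test_union_across_samples(self):
        counts = {"s1": {"E1": 3, "E2": 0}, "s2": {"E2": 1}}
        assert used_exon_ids(counts) == {"E1", "E2"}

    def test_all_zero(self):
        assert used_exon_ids({"s1": {"E1": 0}}) == set()

    def test_single_sample(self):
        assert used_exon_ids({"s1": {"E1": 3, "E2": 0}}) == {"E1"}


class TestTranscriptFilter:
    def _tv(self, tid, eids):
        return TranscriptModel(
            transcript_id=tid,
            gene_id="G",
            exons=[_exon(100 * i, 100 * i + 50, tid=tid, eid=e) for i, e in enumerate(eids)],
        )

    def test_fully_covered_retained(self):
        tv = self._tv("T1", ["E1", "E2", "E3"])
        assert filter_fully_covered_transcripts([tv], {"E1", "E2", "E3"}) == [tv]

    def test_one_uncovered_exon_drops_variant(self):
        tv = self._tv("T1", ["E1", "E2", "E3"])
        assert filter_fully_covered_transcripts([tv], {"E1", "E3"}) == []

    def test_shared_exons_extra_uncovered(self):
        short = self._tv("T1", ["E1", "E2"])
        long = self._tv("T2", ["E0", "E1", "E2"])
        kept = filter_fully_covered_transcripts([short, long], {"E1", "E2"})
        assert kept == [short]


class TestDeriveIntrons:
    def test_gaps_between_exons(self):
        tv = TranscriptModel(
            "T1", "G", [_exon(100, 200), _exon(300, 400), _exon(500, 600)]
        )
        introns = derive_introns(tv)
        assert [(i.interval.start, i.interval.end) for i in introns] == [
            (200, 300),
            (400, 500),
        ]
        assert all(i.feature_type == "intron" for i in introns)
        assert all(i.source == "calculated" for i in introns)
        assert all(i.gene_id == "G" for i in introns)

    def test_single_exon_no_introns(self):
        assert derive_introns(TranscriptModel("T1", "G", [_exon(0, 100)])) == []

    def test_touching_exons_emit_no_intron(self):
        tv = TranscriptModel("T1", "G", [_exon(100, 200), _exon(200, 300)])
        assert derive_introns(tv) == []

    def test_overlapping_exons_rejected(self):
        tv = TranscriptModel("T1", "G", [_exon(100, 200), _exon(150, 300)])
        with pytest.raises(ValueError, match="overlap"):
            derive_introns(tv)


class TestSubtractAmbiguous:
    def test_partial_overlap_trims_both(self):
        ex, intr = subtract_ambiguous([_exon(100, 200)], [_intron(150, 250)])
        assert [(r.interval.start, r.interval.end) for r in ex] == [(100, 150)]
        assert [(r.interval.start, r.interval.end) for r in intr] == [(200, 250)]

    def test_contained_intron_splits_exon(self):
        ex, intr = subtract_ambiguous([_exon(100, 200)], [_intron(120, 180)])
        assert [(r.interval.start, r.interval.end) for r in ex] == [
            (100, 120),
            (180, 200),
        ]
        assert intr == []

    def test_opposite_strand_ignored(self):
        exon, intron = _exon(100, 200, "+"), _intron(150, 250, "-")
        ex, intr = subtract_ambiguous([exon], [intron])
        assert ex == [exon] and intr == [intron]

    def test_directional_counts(self, rng):
        """Ambiguity removal splits introns (count up) and trims exons (count down)."""
        records, _, _ = random_toy_genome(rng, n_genes=10)
        tvs = group_transcripts(records)
        exons = [e for tv in tvs for e in tv.exons]
        introns = [i for tv in tvs for i in derive_introns(tv)]
        ex_u, in_u = subtract_ambiguous(exons, introns)
        assert len(in_u) >= len(introns)
        assert len(ex_u) <= len(exons)

    def test_matches_bedtools_subtract(self, rng, tmp_path):
        """Cross-check against the reference interval toolkit on a random fixture."""
        records, _, _ = random_toy_genome(rng, n_genes=8)
        tvs = group_transcripts(records)
        exons = [e for tv in tvs for e in tv.exons]
        introns = [i for tv in tvs for i in derive_introns(tv)]

        def bed(recs, path):
            rows = sorted(
                (r.interval.chrom, r.interval.start, r.interval.end,
                 r.gene_id, ".", r.interval.strand)
                for r in recs
            )
            path.write_text(
                "".join("\t".join(map(str, row)) + "\n" for row in rows)
            )

        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        bed(exons, a), bed(introns, b)
        out = subprocess.run(
            ["bedtools", "subtract", "-a", str(a), "-b", str(b), "-s"],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = sorted(
            (f[0], int(f[1]), int(f[2]), f[5])
            for f in (line.split("\t") for line in out.splitlines())
        )
        ours = sorted(
            (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand)
            for r in subtract_ambiguous(exons, introns)[0]
        )
        assert ours == expected


class TestCollapseAndMerge:
    def test_overlapping_same_gene_merged(self):
        out = collapse_and_merge([_exon(100, 200), _exon(150, 250)])
        assert [(r.interval.start, r.interval.end) for r in out] == [(100, 250)]
        assert out.features[0].gene_id == "G"

    def test_touching_intervals_merge(self):
        out = collapse_and_merge([_exon(100, 200), _exon(200, 300)])
        assert [(r.interval.start, r.interval.end) for r in out] == [(100, 300)]

    def test_multi_gene_region_dropped(self):
        out = collapse_and_merge([_exon(100, 200, gene="G1"), _exon(150, 250, gene="G2")])
        assert len(out) == 0

    def test_collapsing_never_increases_count(self, rng):
        records, _, _ = random_toy_genome(rng, n_genes=10)
        assert len(collapse_and_merge(records)) <= len(records)


class TestLengthTable:
    def test_half_open_arithmetic(self):
        annotation = collapse_and_merge(
            [_exon(99, 200), _exon(299, 400), _intron(200, 299)]
        )
        table = compute_length_table(annotation)
        assert table.loc["G", "ex_length"] == 202
        assert table.loc["G", "in_length"] == 99

    def test_single_exon_gene_zero_intron(self):
        table = compute_length_table(collapse_and_merge([_exon(0, 100)]))
        assert table.loc["G", "in_length"] == 0

    def test_empty_annotation(self):
        table = compute_length_table(collapse_and_merge([]))
        assert table.empty

    def test_matches_per_base_counting(self, rng):
        records, per_exon, _ = random_toy_genome(rng, n_genes=12)
        annotation, table = build_reference(records, per_exon)
        brute = length_table_bruteforce(annotation)
        for gene, (in_len, ex_len) in brute.items():
            assert table.loc[gene, "in_length"] == in_len
            assert table.loc[gene, "ex_length"] == ex_len


class TestBuildReferenceOracle:
    def test_simple_single_isoform_genome_passthrough(self):
        records = [
            _exon(100, 200, gene="G1", eid="E1"),
            _exon(300, 400, gene="G1", eid="E2"),
        ]
        annotation, lengths = build_reference(records, None)
        tuples = annotation_to_tuples(annotation)
        assert tuples == {
            ("chrT", "+", 100, 200, "exon", "G1"),
            ("chrT", "+", 300, 400, "exon", "G1"),
            ("chrT", "+", 200, 300, "intron", "G1"),
        }
        assert lengths.loc["G1", "in_length"] == 100

    def test_uncovered_variant_and_ambiguity_removed(self):
        # variant T2 has an extra upstream exon with no coverage; its other
        # exons are shared; one cassette exon of T3 sits inside T1's intron
        recs = [
            _exon(1000, 1200, tid="T1", eid="E1"),
            _exon(2000, 2200, tid="T1", eid="E2"),
            _exon(100, 200, tid="T2", eid="E0"),
            _exon(1000, 1200, tid="T2", eid="E1"),
            _exon(2000, 2200, tid="T2", eid="E2"),
            _exon(1000, 1200, tid="T3", eid="E1"),
            _exon(1500, 1600, tid="T3", eid="E3"),
            _exon(2000, 2200, tid="T3", eid="E2"),
        ]
        counts = {"s1": {"E1": 5, "E2": 5, "E3": 2, "E0": 0}}
        annotation, _ = build_reference(recs, counts)
        tuples = annotation_to_tuples(annotation)
        # E0 region gone (T2 dropped); cassette region 1500-1600 ambiguous
        assert ("chrT", "+", 100, 200, "exon", "G") not in tuples
        assert tuples == {
            ("chrT", "+", 1000, 1200, "exon", "G"),
            ("chrT", "+", 2000, 2200, "exon", "G"),
            ("chrT", "+", 1200, 1500, "intron", "G"),
            ("chrT", "+", 1600, 2000, "intron", "G"),
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_per_base_oracle_equivalence(self, seed):
        """Builder output equals brute-force per-base labeling, exactly."""
        rng = np.random.default_rng(1000 + seed)
        records, per_exon, retained = random_toy_genome(rng)
        annotation, _ = build_reference(records, per_exon)
        assert annotation_to_tuples(annotation) == label_reference(retained)

    @pytest.mark.parametrize("seed", range(5))
    def test_final_annotation_disjoint(self, seed):
        rng = np.random.default_rng(2000 + seed)
        records, per_exon, _ = random_toy_genome(rng)
        annotation, _ = build_reference(records, per_exon)
        seen: dict[tuple[str, str], set[int]] = {}
        for rec in annotation:
            iv = rec.interval
            bases = set(range(iv.start, iv.end))
            key = (iv.chrom, iv.strand)
            assert not (seen.setdefault(key, set()) & bases)
            seen[key] |= bases
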