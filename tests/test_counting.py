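"""Fragment assembly and union / intersection-strict counting semantics."""

import numpy as np
import pytest

from inextools.counting import (
    FeatureIndex,
    Fragment,
    assemble_fragments,
    classify_intersection_strict,
    classify_union,
    count_fragments,
)
from inextools.gtf_io import GenomicInterval, GtfRecord

from .conftest import write_sam
from .oracles import classify_strict_bruteforce, classify_union_bruteforce

# flags: 0x1 paired, 0x40/0x80 read1/read2, 0x10 reverse, 0x20 mate reverse
R1_FWD, R2_REV = 0x1 | 0x40 | 0x20, 0x1 | 0x80 | 0x10
R1_REV, R2_FWD = 0x1 | 0x40 | 0x10, 0x1 | 0x80 | 0x20


def _feature(start, end, strand="+", gene="G", ftype="exon"):
    return GtfRecord(
        interval=GenomicInterval("chrT", start, end, strand),
        feature_type=ftype,
        attributes={"gene_id": gene},
    )


class TestAssembleFragments:
    def test_pair_blocks_exclude_inter_mate_gap(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("f1", R1_FWD, 100, "50M"), ("f1", R2_REV, 200, "50M")],
        )
        (frag,) = assemble_fragments(sam, "reverse")
        assert frag.blocks == [(100, 150), (200, 250)]

    def test_junction_cigar_splits_blocks(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("f1", 0, 100, "50M100N50M")])
        (frag,) = assemble_fragments(sam, "unstranded")
        assert frag.blocks == [(100, 150), (250, 300)]

    def test_overlapping_mates_count_bases_once(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [("f1", R1_FWD, 100, "50M"), ("f1", R2_REV, 130, "50M")],
        )
        (frag,) = assemble_fragments(sam, "reverse")
        assert frag.blocks == [(100, 180)]

    @pytest.mark.parametrize(
        "mode,flag1,expected",
        [
            ("reverse", R1_REV, "+"),
            ("reverse", R1_FWD, "-"),
            ("forward", R1_FWD, "+"),
            ("unstranded", R1_FWD, None),
        ],
    )
    def test_library_strand_inference(self, tmp_path, mode, flag1, expected):
        sam = write_sam(tmp_path / "a.sam", [("f1", flag1, 100, "50M")])
        (frag,) = assemble_fragments(sam, mode)
        assert frag.library_strand == expected

    def test_name_regression_detected(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                ("f1", R1_FWD, 100, "50M"),
                ("f2", R1_FWD, 300, "50M"),
                ("f1", R2_REV, 200, "50M"),
            ],
        )
        with pytest.raises(ValueError, match="name-sorted"):
            list(assemble_fragments(sam, "reverse"))

    def test_singleton_mate_yields_fragment(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("f1", R1_FWD, 100, "50M")])
        frags = list(assemble_fragments(sam, "reverse"))
        assert len(frags) == 1 and frags[0].blocks == [(100, 150)]


def _frag(blocks, strand="+"):
    return Fragment(query_name="f", chrom="chrT", blocks=blocks, library_strand=strand)


class TestClassification:
    def setup_method(self):
        self.features = [
            _feature(50, 101, gene="G", ftype="exon"),
            _feature(101, 200, gene="G", ftype="intron"),
        ]
        self.exons = [f for f in self.features if f.feature_type == "exon"]
        self.introns = [f for f in self.features if f.feature_type == "intron"]

    def test_boundary_fragment_counts_in_both_categories(self):
        frag = _frag([(95, 106)])
        assert classify_union(frag, FeatureIndex(self.introns)) == {"G"}
        assert classify_union(frag, FeatureIndex(self.exons)) == {"G"}

    def test_multi_gene_fragment_counts_for_each(self):
        feats = [_feature(0, 100, gene="G1"), _feature(80, 200, gene="G2")]
        assert classify_union(_frag([(85, 95)]), FeatureIndex(feats)) == {"G1", "G2"}

    def test_antisense_fragment_unassigned(self):
        assert classify_union(_frag([(60, 70)], "-"), FeatureIndex(self.exons)) == set()

    def test_strict_fully_inside(self):
        assert classify_intersection_strict(
            _frag([(60, 90)]), FeatureIndex(self.exons)
        ) == {"G"}

    def test_strict_boundary_overhang_empty(self):
        assert (
            classify_intersection_strict(_frag([(95, 106)]), FeatureIndex(self.exons))
            == set()
        )

    def test_strict_junction_spanning(self):
        exons = [_feature(50, 101, gene="G"), _feature(200, 250, gene="G")]
        frag = _frag([(91, 101), (200, 210)])
        assert classify_intersection_strict(frag, FeatureIndex(exons)) == {"G"}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_fragments_match_bruteforce(self, seed):
        """Union and strict sets equal the per-position oracle on 500 random
        fragments over a random overlapping feature set."""
        rng = np.random.default_rng(seed)
        features = []
        for gi in range(15):
            gene = f"G{gi}"
            strand = "+" if rng.random() < 0.5 else "-"
            for _ in range(rng.integers(1, 5)):
                start = int(rng.integers(0, 3000))
                features.append(
                    _feature(start, start + int(rng.integers(10, 400)), strand, gene)
                )
        index = FeatureIndex(features)
        for _ in range(500):
            n_blocks = int(rng.integers(1, 4))
            pos = int(rng.integers(0, 3200))
            blocks = []
            for _ in range(n_blocks):
                length = int(rng.integers(5, 120))
                blocks.append((pos, pos + length))
                pos += length + int(rng.integers(1, 300))
            strand = [None, "+", "-"][int(rng.integers(0, 3))]
            frag = _frag(blocks, strand)
            assert classify_union(frag, index) == classify_union_bruteforce(
                frag, features, "gene_id"
            )
            assert classify_intersection_strict(
                frag, index
            ) == classify_strict_bruteforce(frag, features, "gene_id")
            assert classify_intersection_strict(frag, index) <= classify_union(
                frag, index
            )


class TestCountFragments:
    def _toy(self, tmp_path):
        # gene A exon [100,200) intron [200,300) exon [300,400) on +;
        # gene B exon [600,700) on -
        features = [
            _feature(100, 200, "+", "A", "exon"),
            _feature(300, 400, "+", "A", "exon"),
            _feature(200, 300, "+", "A", "intron"),
            _feature(600, 700, "-", "B", "exon"),
        ]
        reads = [
            ("f1", R1_REV, 110, "40M"),        # inside A exon1 (library +)
            ("f2", R1_REV, 190, "40M"),        # A exon-intron boundary
            ("f3", R1_REV, 150, "50M100N10M"), # junction A exon1->exon2
            ("f4", R1_FWD, 610, "40M"),        # inside B (library -)
            ("f5", R1_FWD, 110, "40M"),        # antisense to A: unassigned
            ("f6", R1_REV, 450, "40M"),        # intergenic
        ]
        sam = write_sam(tmp_path / "toy.sam", reads)
        return sam, features

    def test_counts_match_manual_classification(self, tmp_path):
        sam, features = self._toy(tmp_path)
        exons = [f for f in features if f.feature_type == "exon"]
        introns = [f for f in features if f.feature_type == "intron"]
        ex_union = count_fragments(sam, exons, mode="union")
        in_union = count_fragments(sam, introns, mode="union")
        ex_strict = count_fragments(sam, exons, mode="intersection_strict")
        assert ex_union.to_dict() == {"A": 3, "B": 1}  # f1, f2, f3 / f4
        assert in_union.to_dict() == {"A": 1}          # f2 only
        assert ex_strict.to_dict() == {"A": 2, "B": 1}  # f1, f3 / f4
        # strict is a subset of union per gene
        assert (ex_strict <= ex_union[ex_strict.index]).all()

    def test_duplicate_fragment_adds_one_count(self, tmp_path):
        features = [_feature(100, 200, "+", "A", "exon")]
        sam1 = write_sam(tmp_path / "one.sam", [("f1", R1_REV, 110, "40M")])
        sam2 = write_sam(
            tmp_path / "two.sam",
            [("f1", R1_REV, 110, "40M"), ("f2", R1_REV, 110, "40M")],
        )
        assert count_fragments(sam2, features)["A"] == count_fragments(sam1, features)["A"] + 1

    def test_strand_mode_flip_zeroes_counts(self, tmp_path):
        # antisense-free fixture: every fragment is sense under reverse mode
        _, features = self._toy(tmp_path)
        sam = write_sam(
            tmp_path / "sense.sam",
            [
                ("f1", R1_REV, 110, "40M"),
                ("f2", R1_REV, 190, "40M"),
                ("f3", R1_FWD, 610, "40M"),
            ],
        )
        rev = count_fragments(sam, features, mode="union", strandedness="reverse")
        fwd = count_fragments(sam, features, mode="union", strandedness="forward")
        assert rev.sum() == 3
        assert fwd.sum() == 0

    def test_zero_count_keys_present(self, tmp_path):
        features = [_feature(100, 200, "+", "A"), _feature(5000, 6000, "+", "Z")]
        sam = write_sam(tmp_path / "a.sam", [("f1", R1_REV, 110, "40M")])
        counts = count_fragments(sam, features)
        assert counts["Z"] == 0

    def test_empty_annotation_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("f1", R1_REV, 110, "40M")])
        with pytest.raises(ValueError, match="empty"):
            count_fragments(sam, [])
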