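"""miRNA quantification, isomiR end-offset classification, enrichment."""

import numpy as np
import pandas as pd
import pytest

import srnafrac as sf
from srnafrac.mirna import MirnaAnnotation, end_offsets
from srnafrac.normalization import NormFactor
from srnafrac.records import AlignmentRecord

MIR_PLUS = MirnaAnnotation("miR-plus", "chr1", "+", 1000, 1021)
MIR_MINUS = MirnaAnnotation("miR-minus", "chr1", "-", 2000, 2021)


def _read_for(mir: MirnaAnnotation, d5: int, d3: int, copies: int = 1) -> AlignmentRecord:
    if mir.strand == "+":
        start, end = mir.start + d5, mir.end + d3
    else:
        start, end = mir.start - d3, mir.end - d5
    return AlignmentRecord(mir.chrom, start, end - start, mir.strand, copies=copies)


@pytest.mark.parametrize("mir", [MIR_PLUS, MIR_MINUS], ids=["plus", "minus"])
@pytest.mark.parametrize(
    "d5, d3, label, category",
    [
        (0, 0, "m_0_0", "annotated"),
        (-1, 0, "m_-1_0", "5p_extension"),
        (0, 1, "m_0_1", "3p_extension"),
        (1, 0, "m_1_0", "5p_trim"),
        (0, -1, "m_0_-1", "3p_trim"),
        (-1, 1, "m_-1_1", "shifted"),
        (1, -1, "m_1_-1", "shifted"),
    ],
)
def test_offsets_labels_and_categories(mir, d5, d3, label, category):
    read = _read_for(mir, d5, d3)
    assert end_offsets(read, mir) == (d5, d3)
    lab = sf.classify_isoform(read, mir)
    assert (lab.label, lab.category) == (label, category)
    # length identity for every counted read
    assert read.length == mir.annotated_length - d5 + d3


def test_classify_outside_tolerance_is_error():
    read = _read_for(MIR_PLUS, 1, 2)
    with pytest.raises(ValueError, match="tolerance"):
        sf.classify_isoform(read, MIR_PLUS)


class TestQuantify:
    def test_exact_match_and_isoforms_counted(self):
        reads = [
            _read_for(MIR_PLUS, 0, 0, copies=9),
            _read_for(MIR_PLUS, 0, 1, copies=4),  # 22-nt 3' extension
            _read_for(MIR_MINUS, -1, 0, copies=2),
        ]
        q = sf.quantify_mirna(reads, [MIR_PLUS, MIR_MINUS])
        q = q.set_index(["mirna_id", "label"])
        assert q.loc[("miR-plus", "m_0_0"), "raw"] == 9
        assert q.loc[("miR-plus", "m_0_1"), "raw"] == 4
        assert q.loc[("miR-plus", "m_0_1"), "length"] == 22
        assert q.loc[("miR-minus", "m_-1_0"), "raw"] == 2

    def test_offsets_beyond_tolerance_not_counted(self):
        q = sf.quantify_mirna([_read_for(MIR_PLUS, -2, 0)], [MIR_PLUS])
        assert q.empty
        # admitted at a wider tolerance
        q2 = sf.quantify_mirna([_read_for(MIR_PLUS, -2, 0)], [MIR_PLUS], shift_tol=2)
        assert q2.iloc[0]["label"] == "m_-2_0"

    def test_m_1_2_only_with_wider_tolerance(self):
        read = _read_for(MIR_PLUS, 1, 2)
        assert sf.quantify_mirna([read], [MIR_PLUS]).empty
        q = sf.quantify_mirna([read], [MIR_PLUS], shift_tol=2)
        assert q.iloc[0]["label"] == "m_1_2"

    def test_wrong_strand_or_chrom_not_counted(self):
        read = AlignmentRecord("chr1", 1000, 21, "-")
        assert sf.quantify_mirna([read], [MIR_PLUS]).empty

    def test_ambiguity_resolved_by_minimal_offset_then_id(self):
        other = MirnaAnnotation("miR-aaa", "chr1", "+", 1001, 1022)
        read = AlignmentRecord("chr1", 1001, 21, "+")  # exact for other, (1,1) for MIR_PLUS
        q = sf.quantify_mirna([read], [MIR_PLUS, other])
        assert list(q["mirna_id"]) == ["miR-aaa"]
        # exact tie: both annotations at identical coordinates -> lexical first
        twin = MirnaAnnotation("miR-zzz", "chr1", "+", 1000, 1021)
        q2 = sf.quantify_mirna([_read_for(MIR_PLUS, 0, 0)], [twin, MIR_PLUS])
        assert list(q2["mirna_id"]) == ["miR-plus"]

    def test_genome_sequence_check_rejects_mismatch(self):
        genome = {"chr1": "A" * 3000}
        ok = AlignmentRecord("chr1", 1000, 21, "+", sequence="A" * 21)
        bad = AlignmentRecord("chr1", 1000, 21, "+", sequence="A" * 20 + "C")
        q = sf.quantify_mirna([ok, bad], [MIR_PLUS], genome=genome)
        assert q["raw"].sum() == 1

    def test_additivity_over_concatenated_streams(self, rng):
        reads1 = [_read_for(MIR_PLUS, 0, 0, copies=int(rng.integers(1, 5))) for _ in range(20)]
        reads2 = [_read_for(MIR_PLUS, 0, 1, copies=int(rng.integers(1, 5))) for _ in range(20)]
        q_all = sf.quantify_mirna(reads1 + reads2, [MIR_PLUS])
        q1 = sf.quantify_mirna(reads1, [MIR_PLUS])
        q2 = sf.quantify_mirna(reads2, [MIR_PLUS])
        assert q_all["raw"].sum() == q1["raw"].sum() + q2["raw"].sum()


def test_isoform_fraction_table():
    q = pd.DataFrame(
        {
            "mirna_id": ["m1", "m1"],
            "d5": [0, 0],
            "d3": [0, 1],
            "label": ["m_0_0", "m_0_1"],
            "category": ["annotated", "3p_extension"],
            "length": [21, 22],
            "raw": [90, 10],
        }
    )
    lengths, cats = sf.isoform_fraction_table(q)
    by_len = lengths.set_index("length")["fraction"]
    assert by_len[21] == pytest.approx(0.9)
    assert by_len[22] == pytest.approx(0.1)
    assert cats["fraction"].sum() == pytest.approx(1.0)
    empty_lengths, empty_cats = sf.isoform_fraction_table(q.iloc[0:0])
    assert empty_lengths.empty and empty_cats.empty


class TestEnrichmentRatio:
    def test_ratio_of_rpmr_values(self):
        # 4000 raw / 0.1M rRNA = 40 RPMR vs 2000 raw / 0.1M = 20 RPMR
        f = NormFactor("x", 100_000, 10**6)
        table = sf.enrichment_ratio({"m1": 4000}, {"m1": 2000}, f, f)
        assert table.iloc[0]["ratio"] == pytest.approx(2.0, rel=1e-3)

    def test_identity_and_omission(self):
        f = NormFactor("x", 10**6, 10**6)
        table = sf.enrichment_ratio({"m1": 50, "m2": 0}, {"m1": 50, "m2": 0}, f, f)
        assert list(table["feature_id"]) == ["m1"]  # absent in both -> omitted
        assert table.iloc[0]["ratio"] == pytest.approx(1.0)
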