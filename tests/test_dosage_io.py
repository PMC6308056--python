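"""Marker-id parsing, dosage file round-trips, grouping and alignment."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlafinemap.dosage_io import (
    DosageFormatError,
    MarkerParseError,
    MultiAllelicGroup,
    VariantKind,
    align,
    format_marker_id,
    group_multiallelic,
    parse_marker_id,
    read_dosage,
    read_pheno,
    write_dosage,
)
from simhelpers import make_panel


@pytest.mark.parametrize(
    "marker_id, kind, checks",
    [
        (
            "AA_A_62_30019970_Q",
            VariantKind.AA,
            dict(locus="A", aa_position=62, residue="Q", genomic_position=30019970),
        ),
        (
            "AA_B_-16_31432000_L",
            VariantKind.AA,
            dict(locus="B", aa_position=-16, residue="L"),
        ),
        ("AA_DRB1_67_32660100", VariantKind.AA, dict(aa_position=67, residue=None)),
        (
            "HLA_DQB1_0301",
            VariantKind.HLA_ALLELE,
            dict(locus="DQB1", allele_digits="four", allele_name="DQB1*03:01"),
        ),
        (
            "HLA_A_11",
            VariantKind.HLA_ALLELE,
            dict(allele_digits="two", allele_name="A*11"),
        ),
        ("rs2894207", VariantKind.SNP, dict(locus="intergenic")),
        ("SNP_A_30018000", VariantKind.SNP, dict(locus="A", genomic_position=30018000)),
    ],
)
def test_parse_marker_id(marker_id, kind, checks):
    meta = parse_marker_id(marker_id)
    assert meta.kind is kind
    for attr, expected in checks.items():
        assert getattr(meta, attr) == expected
    assert format_marker_id(meta) == marker_id


@pytest.mark.parametrize(
    "bad", ["", "AA_A_62", "AA_A_x_30019970_Q", "HLA_DQB1_031", "HLA_A", "AA_A_62_pos_Q"]
)
def test_malformed_ids_rejected(bad):
    with pytest.raises(MarkerParseError):
        parse_marker_id(bad)


@settings(deadline=None, max_examples=200)
@given(
    st.one_of(
        st.builds(
            lambda loc, pos, g, res: f"AA_{loc}_{pos}_{g}" + (f"_{res}" if res else ""),
            st.sampled_from(["A", "B", "C", "DRB1", "DQB1"]),
            st.integers(-30, 300),
            st.integers(1, 40_000_000),
            st.sampled_from(["", "Q", "x", "FY"]),
        ),
        st.builds(
            lambda loc, d: f"HLA_{loc}_{d}",
            st.sampled_from(["A", "B", "DPA1"]),
            st.sampled_from(["01", "11", "0301", "1101"]),
        ),
        st.builds(lambda n: f"rs{n}", st.integers(1, 10**8)),
    )
)
def test_parse_format_roundtrip(marker_id):
    assert format_marker_id(parse_marker_id(marker_id)) == marker_id


def _write_files(tmp_path, dosage_text, sample_text="s1\ns2\ns3\ns4\n"):
    d = tmp_path / "d.dosage"
    s = tmp_path / "d.sample"
    d.write_text(dosage_text)
    s.write_text(sample_text)
    return d, s


def test_read_dosage_shape(tmp_path):
    d, s = _write_files(
        tmp_path,
        "rs1 A G 0.0 1.0 2.0 0.5\n"
        "AA_A_62_30019970_Q P A 1.1 0.9 NA 2.0\n"
        "HLA_A_1101 P A 0 1 2 1\n",
    )
    panel = read_dosage(d, s)
    assert panel.dosage.shape == (3, 4)
    assert np.isnan(panel.get_dosage("AA_A_62_30019970_Q")[2])
    assert panel.alleles[0] == ("A", "G")


def test_read_dosage_rejects_out_of_bounds(tmp_path):
    d, s = _write_files(tmp_path, "rs1 A G 0.0 1.0 2.3 0.5\n")
    with pytest.raises(DosageFormatError, match="outside"):
        read_dosage(d, s)


def test_read_dosage_rejects_bad_row_length(tmp_path):
    d, s = _write_files(tmp_path, "rs1 A G 0.0 1.0 2.0\n")
    with pytest.raises(DosageFormatError, match="line 1"):
        read_dosage(d, s)


def test_read_dosage_rejects_duplicate_marker(tmp_path):
    d, s = _write_files(tmp_path, "rs1 A G 0 1 2 0\nrs1 A G 0 1 2 0\n")
    with pytest.raises(DosageFormatError, match="duplicate"):
        read_dosage(d, s)


def test_write_read_roundtrip_token_identical(tmp_path):
    panel = make_panel(
        {
            "rs1": [0.123, 1.0, 2.0, np.nan],
            "AA_A_62_30019970_Q": [0.5, 1.5, 0.0, 2.0],
        }
    )
    d1, s1 = tmp_path / "a.dosage", tmp_path / "a.sample"
    write_dosage(panel, d1, s1)
    panel2 = read_dosage(d1, s1)
    d2, s2 = tmp_path / "b.dosage", tmp_path / "b.sample"
    write_dosage(panel2, d2, s2)
    assert d1.read_text() == d2.read_text()
    assert s1.read_text() == s2.read_text()
    # matrix preserved bit-exactly at the written precision
    np.testing.assert_array_equal(
        np.nan_to_num(panel2.dosage), np.nan_to_num(panel.dosage)
    )


def test_group_multiallelic_three_residues():
    panel = make_panel(
        {
            "AA_A_62_30019970_L": [1, 0, 0, 1],
            "AA_A_62_30019970_Q": [1, 2, 1, 0],
            "AA_A_62_30019970_R": [0, 0, 1, 1],
            "AA_B_45_31430000_P": [0, 1, 2, 1],  # lone residue: no group
        }
    )
    groups = group_multiallelic(panel)
    assert len(groups) == 1
    g = groups[0]
    assert isinstance(g, MultiAllelicGroup)
    assert (g.locus, g.aa_position, g.m) == ("A", 62, 3)
    assert [v.residue for v in g.members] == ["L", "Q", "R"]


def test_two_residue_position_stays_biallelic():
    panel = make_panel(
        {"AA_A_9_30018000_P": [1, 1], "AA_A_9_30018000_A": [1, 1]}
    )
    assert group_multiallelic(panel) == []


def test_group_multiallelic_empty_panel():
    panel = make_panel({})
    assert group_multiallelic(panel) == []


def test_pheno_align_and_errors(tmp_path, caplog):
    p = tmp_path / "pheno.tsv"
    p.write_text(
        "sample_id\tstatus\tage\tgender\n"
        + "".join(f"s{i}\t{i % 2}\t{40 + i}\t{i % 2}\n" for i in range(1, 6))
    )
    pheno = read_pheno(p)
    assert len(pheno) == 5

    panel = make_panel(
        {"rs1": [0, 1, 2, 1]}, sample_ids=["s1", "s2", "s3", "s4"]
    )
    with caplog.at_level(logging.WARNING):
        aligned, df = align(panel, pheno)
    assert aligned.n_samples == 4 and len(df) == 4
    assert "dropped" in caplog.text
    assert list(df.index) == ["s1", "s2", "s3", "s4"]

    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tstatus\tage\tgender\ns1\t3\t50\t0\n")
    with pytest.raises(DosageFormatError, match="status"):
        read_pheno(bad)
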