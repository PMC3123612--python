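"""I/O contracts for .dta, .out and pix files."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pival import msio
from pival.msio import (
    FormatError,
    Peak,
    PixRecord,
    Spectrum,
    pair_inputs,
    read_dta,
    read_out,
    read_pix,
    strip_flanks,
    write_dta,
    write_pix,
)

OUT_TEXT = """synthetic SEQUEST result
 (M+H)+ mass = 694.345678  charge = 2

  Rank     (M+H)+    deltCn   XCorr       Sp   Ions  Reference        Peptide
  ----     ------    ------   -----       --   ----  ---------        -------
  1     694.345678   0.0000  2.5000    512.3  12/24  PROTA            K.ACDEFK.L
  2     694.345678   0.2400  1.9000    410.0  10/24  rev_PROTB        K.CADEFK.L
"""


# ---------------------------------------------------------------------- .dta

def test_read_dta_transcribes_header_and_peaks(tmp_path):
    f = tmp_path / "a.dta"
    f.write_text("147.076 1\n72.044 120.0\n76.039 200.0\n")
    s = read_dta(f)
    assert s.precursor_mh == pytest.approx(147.076)
    assert s.charge == 1
    assert [(p.mz, p.intensity) for p in s.peaks] == [(72.044, 120.0), (76.039, 200.0)]


def test_read_dta_sorts_descending_input_and_skips_comments(tmp_path):
    f = tmp_path / "a.dta"
    f.write_text("# fixture\n500.0 2\n\n300.0 5.0  # second peak\n200.0 9.0\n")
    s = read_dta(f)
    assert [p.mz for p in s.peaks] == [200.0, 300.0]


@pytest.mark.parametrize("text,fragment", [
    ("bad header\n100 1\n", "line 1"),
    ("500.0 2\n100 not_a_number\n", "line 2"),
    ("500.0 2\n", "no peaks"),
])
def test_read_dta_format_errors_name_the_line(tmp_path, text, fragment):
    f = tmp_path / "a.dta"
    f.write_text(text)
    with pytest.raises(FormatError, match=fragment):
        read_dta(f)


@given(st.lists(
    st.tuples(st.floats(50, 2000), st.floats(0, 1e6)),
    min_size=1, max_size=30, unique_by=lambda t: round(t[0], 6)))
def test_dta_round_trip_to_six_decimals(tmp_path_factory, peak_tuples):
    spectrum = Spectrum("rt", 1500.0, 2,
                        [Peak(mz, i) for mz, i in peak_tuples])
    f = tmp_path_factory.mktemp("dta") / "rt.dta"
    write_dta(spectrum, f)
    back = read_dta(f)
    assert back.charge == spectrum.charge
    assert back.precursor_mh == pytest.approx(spectrum.precursor_mh, abs=1e-6)
    assert len(back.peaks) == len(spectrum.peaks)
    for a, b in zip(back.peaks, spectrum.peaks):
        assert a.mz == pytest.approx(b.mz, abs=1e-6)
        assert a.intensity == pytest.approx(b.intensity, abs=1e-6)


# ---------------------------------------------------------------------- .out

def test_read_out_transcribes_hits_in_rank_order(tmp_path):
    f = tmp_path / "a.out"
    f.write_text(OUT_TEXT)
    out = read_out(f)
    assert out.spectrum_id == "a"
    assert out.precursor_mh == pytest.approx(694.345678)
    assert out.charge == 2
    assert [h.rank for h in out.hits] == [1, 2]
    assert [h.xcorr for h in out.hits] == [2.5, 1.9]
    # no silently dropped rows
    assert len(out.hits) == 2


def test_delta_cn_of_rank1_comes_from_rank2_row(tmp_path):
    f = tmp_path / "a.out"
    f.write_text(OUT_TEXT)
    hits = read_out(f).hits
    assert hits[0].delta_cn == pytest.approx(0.24)
    assert hits[1].delta_cn == 1.0  # last hit


def test_single_hit_gets_delta_cn_one(tmp_path):
    text = "\n".join(OUT_TEXT.splitlines()[:6]) + "\n"
    f = tmp_path / "b.out"
    f.write_text(text)
    hits = read_out(f).hits
    assert len(hits) == 1
    assert hits[0].delta_cn == 1.0


def test_peptide_token_flank_stripping():
    assert strip_flanks("K.ACDEFK.L") == ("ACDEFK", "K", "L")
    assert strip_flanks("-.ACDEFK.L") == ("ACDEFK", "-", "L")
    assert strip_flanks("ACDEFK") == ("ACDEFK", "-", "-")


def test_read_out_without_hit_table_raises(tmp_path):
    f = tmp_path / "a.out"
    f.write_text("just a header\nno table here\n")
    with pytest.raises(FormatError, match="table"):
        read_out(f)


def test_read_out_unparseable_score_field_names_the_row(tmp_path):
    bad = OUT_TEXT.replace("2.5000", "oops")
    f = tmp_path / "a.out"
    f.write_text(bad)
    with pytest.raises(FormatError, match="score field"):
        read_out(f)


# ------------------------------------------------------------------- pairing

def _write_pair(d, stem, peptide="ACDEFK"):
    (d / f"{stem}.dta").write_text("694.345678 2\n100.0 10.0\n")
    (d / f"{stem}.out").write_text(OUT_TEXT)


def test_pair_inputs_warns_on_unpaired_files(tmp_path):
    _write_pair(tmp_path, "a")
    (tmp_path / "b.dta").write_text("694.345678 2\n100.0 10.0\n")
    with pytest.warns(UserWarning, match="unpaired"):
        psms = pair_inputs(tmp_path)
    assert len(psms) == 1
    assert psms[0].hit.rank == 1
    assert psms[0].is_decoy is False


def test_pair_inputs_empty_directory(tmp_path):
    with pytest.warns(UserWarning, match="no .dta/.out pairs"):
        assert pair_inputs(tmp_path) == []


def test_pair_inputs_missing_directory_raises(tmp_path):
    with pytest.raises(IOError):
        pair_inputs(tmp_path / "nope")


def test_decoy_detection_uses_protein_prefix(tmp_path):
    _write_pair(tmp_path, "a")
    psms = pair_inputs(tmp_path, top_n=2)
    assert [p.is_decoy for p in psms] == [False, True]


# ----------------------------------------------------------------------- pix

def _record(i=0, proteins=("PROTA", "rev_PROTB")):
    return PixRecord(spectrum_id=f"spec{i}", peptide="ACDEFK", xcorr=2.5,
                     delta_cn=0.24, sp=512.3, pi_score=0.87,
                     proteins=list(proteins))


def test_pix_round_trip_single_record(tmp_path):
    f = tmp_path / "r.pix"
    write_pix([_record()], f, meta={"train_size": 3000})
    back = read_pix(f)
    assert back == [_record()]
    assert msio.read_pix_meta(f)["train_size"] == "3000"


def test_pix_empty_protein_list_is_valid(tmp_path):
    f = tmp_path / "r.pix"
    write_pix([_record(proteins=())], f)
    assert read_pix(f)[0].proteins == []


def test_pix_write_requires_records(tmp_path):
    with pytest.raises(ValueError):
        write_pix([], tmp_path / "r.pix")


def test_pix_malformed_xml_raises(tmp_path):
    f = tmp_path / "r.pix"
    f.write_text("<pix><psm></pix>")
    with pytest.raises(FormatError):
        read_pix(f)


@given(st.lists(
    st.tuples(
        st.text(alphabet="abcdefgh0123456789_", min_size=1, max_size=12),
        st.floats(0, 20), st.floats(0, 1), st.floats(0, 1),
        st.lists(st.text(alphabet="ABCdef_123", min_size=1, max_size=10), max_size=3),
    ),
    min_size=1, max_size=40))
def test_pix_round_trip_property(tmp_path_factory, rows):
    records = [
        PixRecord(spectrum_id=sid, peptide="ACDK", xcorr=x, delta_cn=d,
                  sp=None, pi_score=s, proteins=prots)
        for sid, x, d, s, prots in rows
    ]
    f = tmp_path_factory.mktemp("pix") / "r.pix"
    write_pix(records, f)
    back = read_pix(f)
    assert len(back) == len(records)
    for a, b in zip(back, records):
        assert a.spectrum_id == b.spectrum_id
        assert a.proteins == b.proteins
        assert a.sp is None
        for attr in ("xcorr", "delta_cn", "pi_score"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-9, abs=1e-12)
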