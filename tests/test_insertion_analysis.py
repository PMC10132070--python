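"""IS copy location, flanks, TSD calling and dif-target association."""

from __future__ import annotations

import numpy as np
import pytest

from difhunter.dif_scanner import BindingSiteModel
from difhunter.insertion_analysis import (ISCopy, analyze_insertions,
                                          call_tsd, classify_subgroup,
                                          extract_flanks, locate_is_copies,
                                          targeting_report)
from difhunter.registry import diflike_site_survey, pdif_site_survey, survey_row
from difhunter.seqcore import Sequence, revcomp
from difhunter.synthetic_data import ISProfile, make_background, make_is_element

from conftest import mutate, random_dna


@pytest.fixture(scope="module")
def isajo2():
    elem, _ = make_is_element(ISProfile.preset("ISAjo2"), seed=1)
    return elem


def _reconstruct(row, elem, seed=0):
    """pad - TSD - IS - TSD - C/spacer/D - pad, per the printed survey."""
    rng = np.random.default_rng(seed)
    pad1 = make_background(rng, "p", 60).residues
    pad2 = make_background(rng, "p", 60).residues
    locus = (pad1 + row["tsd"] + elem.residues + row["tsd"]
             + row["xerC"] + row["spacer"] + row["xerD"] + pad2)
    return Sequence(id=row["accession"], residues=locus)


# --- locate_is_copies -----------------------------------------------------

def test_exact_copy_found_with_full_identity(isajo2, rng):
    bg = make_background(rng, "rep", 4000).residues
    rep = Sequence(id="rep", residues=bg[:1500] + isajo2.residues + bg[1500:])
    copies = locate_is_copies(rep, isajo2)
    assert [(c.start, c.end, c.strand) for c in copies] == \
        [(1500, 1500 + len(isajo2), "+")]
    assert copies[0].identity_to_query == 100.0
    assert copies[0].coverage == 100.0


@pytest.mark.parametrize("seed", range(10))
def test_two_percent_diverged_copy_detected(seed, isajo2):
    rng = np.random.default_rng(seed)
    diverged = mutate(isajo2.residues, 0.02, rng)
    bg = make_background(rng, "rep", 3000).residues
    rep = Sequence(id="rep", residues=bg[:800] + diverged + bg[800:])
    copies = locate_is_copies(rep, isajo2, min_identity=95)
    assert len(copies) == 1
    assert copies[0].identity_to_query == pytest.approx(98.0, abs=0.7)


def test_minus_strand_copy_same_span(isajo2, rng):
    bg = make_background(rng, "rep", 3000).residues
    rep_f = Sequence(id="r", residues=bg[:900] + isajo2.residues + bg[900:])
    rep_r = Sequence(id="r", residues=bg[:900] + revcomp(isajo2.residues) + bg[900:])
    fwd = locate_is_copies(rep_f, isajo2)[0]
    rev = locate_is_copies(rep_r, isajo2)[0]
    assert (rev.start, rev.end) == (fwd.start, fwd.end)
    assert rev.strand == "-"


def test_query_size_guard(isajo2, rng):
    with pytest.raises(ValueError):
        locate_is_copies(Sequence(id="r", residues=random_dna(rng, 500)),
                         random_dna(rng, 100))


# --- flanks ---------------------------------------------------------------

def test_flanks_match_construction(isajo2, rng):
    left = random_dna(rng, 50)
    right = random_dna(rng, 50)
    rep = Sequence(id="r", residues=random_dna(rng, 200) + left
                   + isajo2.residues + right + random_dna(rng, 200))
    copy = locate_is_copies(rep, isajo2)[0]
    lf, rf, lt, rt = extract_flanks(rep, copy)
    assert (lf, rf) == (left, right)
    assert not lt and not rt


def test_minus_strand_flanks_are_swapped_and_complemented(isajo2, rng):
    left = random_dna(rng, 50)
    right = random_dna(rng, 50)
    rep = Sequence(id="r", residues=random_dna(rng, 200) + left
                   + revcomp(isajo2.residues) + right + random_dna(rng, 200))
    copy = locate_is_copies(rep, isajo2)[0]
    lf, rf, _, _ = extract_flanks(rep, copy)
    # in the element's own orientation, its left flank is revcomp(right)
    assert (lf, rf) == (revcomp(right), revcomp(left))


def test_circular_flank_wraps_origin(isajo2):
    rng = np.random.default_rng(5)
    bg = make_background(rng, "r", 300).residues
    rep = Sequence(id="r", residues=isajo2.residues + bg, topology="circular")
    copy = ISCopy(replicon_id="r", start=0, end=len(isajo2), strand="+",
                  identity_to_query=100, coverage=100)
    lf, rf, lt, rt = extract_flanks(rep, copy)
    assert lf == bg[-50:]
    assert rf == bg[:50]
    assert not lt and not rt


def test_linear_flank_truncation_flagged(isajo2):
    copy = ISCopy(replicon_id="r", start=0, end=len(isajo2), strand="+",
                  identity_to_query=100, coverage=100)
    rep = Sequence(id="r", residues=isajo2.residues + "ACGT" * 20)
    lf, rf, lt, rt = extract_flanks(rep, copy)
    assert lf == "" and lt
    assert len(rf) == 50 and not rt
    with pytest.raises(ValueError):
        extract_flanks(rep, copy, w=0)


# --- call_tsd -------------------------------------------------------------

def test_call_tsd_examples():
    assert call_tsd("GGGGGAACGC", "AACGCATTTC") == ("AACGC", 5)
    assert call_tsd("AAAAAC", "GAAAAA") == ("", 0)
    dup = "TATCCGGTTAACGGATCCAAGGTTCCA"  # 27 bp, long-TSD profile scale
    assert call_tsd("G" + dup, dup + "C") == (dup, 27)


@pytest.mark.parametrize("seed", range(15))
def test_call_tsd_symmetric_under_revcomp_swap(seed):
    rng = np.random.default_rng(seed)
    lf, rf = random_dna(rng, 50), random_dna(rng, 50)
    _, k = call_tsd(lf, rf)
    _, k2 = call_tsd(revcomp(rf), revcomp(lf))
    assert k == k2


# --- subgrouping ----------------------------------------------------------

@pytest.mark.parametrize("tsd_len,label,in_band", [
    (5, "short", True), (3, "short", True), (8, "short", False),
    (27, "long", True), (16, "long", True), (0, "none", True),
])
def test_classify_subgroup(tsd_len, label, in_band):
    call = classify_subgroup(tsd_len)
    assert (call.label, call.in_expected_band) == (label, in_band)


def test_classify_subgroup_rejects_negative():
    with pytest.raises(ValueError):
        classify_subgroup(-1)


# --- target association on printed survey loci ---------------------------

def test_pS30_1_style_locus_reconstruction(isajo2):
    row = survey_row(pdif_site_survey(), "ISAba71", "KY617771(1)")
    rep = _reconstruct(row, isajo2)
    ctxs = analyze_insertions(rep, isajo2, model=BindingSiteModel.dif_like())
    assert len(ctxs) == 1
    ctx = ctxs[0]
    assert (ctx.tsd_seq, ctx.tsd_len) == ("AACGC", 5)
    assert ctx.distance_to_xerC == 5
    assert ctx.orientation_consistent
    assert ctx.site.xerD == "TTATGTTAAAT" and ctx.site.mm_D == 0


def test_hi1_plasmid_diflike_locus_reconstruction():
    elem, _ = make_is_element(ISProfile.preset("ISSen13"), seed=1)
    row = survey_row(diflike_site_survey(), "ISSen13", "CP058810")
    rep = _reconstruct(row, elem)
    ctxs = analyze_insertions(rep, elem, model=BindingSiteModel.dif_like())
    assert len(ctxs) == 1
    assert ctxs[0].tsd_len == 3
    assert ctxs[0].distance_to_xerC == 3
    assert ctxs[0].orientation_consistent


def test_untargeted_insertion_has_no_site(isajo2, rng):
    bg = make_background(rng, "rep", 3000).residues
    rep = Sequence(id="rep", residues=bg[:1000] + isajo2.residues + bg[1000:])
    ctxs = analyze_insertions(rep, isajo2)
    assert len(ctxs) == 1
    assert ctxs[0].site is None
    assert ctxs[0].distance_to_xerC is None
    assert not ctxs[0].orientation_consistent


def test_no_copies_no_contexts(isajo2, rng):
    rep = make_background(rng, "rep", 4000)
    assert analyze_insertions(rep, isajo2) == []


# --- report ---------------------------------------------------------------

def test_targeting_report_reproduces_printed_rows(isajo2):
    df = pdif_site_survey()
    rows = [survey_row(df, "ISAba71", "KY617771(1)"),
            survey_row(df, "ISAba32", "CP051211"),
            survey_row(df, "ISAlw22", "CP054822")]
    ctxs = []
    for i, row in enumerate(rows):
        rep = _reconstruct(row, isajo2, seed=i)
        ctxs.extend(analyze_insertions(rep, isajo2))
    table = targeting_report(ctxs)
    assert list(table["tsd"]) == [r["tsd"] for r in rows]
    assert list(table["xerC"]) == [r["xerC"] for r in rows]
    assert list(table["spacer"]) == [r["spacer"] for r in rows]
    assert list(table["xerD"]) == [r["xerD"] for r in rows]
    assert list(table["distance_to_xerC"]) == [5, 5, 5]
    assert all(table["orientation_consistent"])
    assert all(table["subgroup"] == "short")


def test_targeting_report_empty_has_header():
    table = targeting_report([])
    assert len(table) == 0
    assert "tsd" in table.columns and "xerC" in table.columns
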