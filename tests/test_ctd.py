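"""CTD descriptor tests: worked example, edge cases, brute-force oracle,
and invariance properties."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protstab import (
    GROUPINGS,
    HYDROPHOBICITY,
    ProteinRecord,
    SOLVENT_ACCESSIBILITY,
    aac_vector,
    biochemical_vector,
    composition,
    ctd_block,
    distribution,
    encode_sequence,
    transition,
)
from protstab.ctd import AAC_ORDER, EncodingError, biochemical_feature_names
from protstab.records import AMINO_ACIDS, SequenceError, make_record, propensity_tracks

from conftest import WORKED_CODED, WORKED_SEQUENCE

PNH = ("P", "N", "H")


# ---------------------------------------------------------------------------
# independent oracle: plain-loop CTD on a coded string, exact rationals

def oracle_ctd(coded: str, categories: tuple[str, ...]):
    n = len(coded)
    comp = [Fraction(sum(1 for c in coded if c == cat), n) for cat in categories]
    trans_pairs = list(combinations(categories, 2))
    diffs = [(coded[i], coded[i + 1]) for i in range(n - 1) if coded[i] != coded[i + 1]]
    tran = []
    for a, b in trans_pairs:
        k = sum(1 for x, y in diffs if {x, y} == {a, b})
        tran.append(Fraction(k, len(diffs)) if diffs else Fraction(0))
    dist = []
    for cat in categories:
        occ = [i + 1 for i, c in enumerate(coded) if c == cat]
        if not occ:
            dist += [Fraction(0)] * 5
        else:
            for q in (Fraction(0), Fraction(1, 4), Fraction(1, 2), Fraction(3, 4), Fraction(1)):
                k = max(1, math.ceil(q * len(occ)))
                dist.append(Fraction(occ[k - 1], n))
    return comp, tran, dist


# ---------------------------------------------------------------------------
# worked example

class TestWorkedExample:
    def test_hydrophobicity_coding(self, worked_record):
        assert encode_sequence(worked_record, HYDROPHOBICITY) == WORKED_CODED

    def test_category_counts(self):
        assert WORKED_CODED.count("H") == 10
        assert WORKED_CODED.count("N") == 16
        assert WORKED_CODED.count("P") == 24

    def test_composition(self):
        np.testing.assert_allclose(
            composition(WORKED_CODED, PNH), [0.48, 0.32, 0.20], atol=1e-15
        )

    def test_transition_total_and_fractions(self):
        diffs = sum(1 for a, b in zip(WORKED_CODED, WORKED_CODED[1:]) if a != b)
        assert diffs == 31
        # pair order PN, PH, NH
        np.testing.assert_allclose(
            transition(WORKED_CODED, PNH), [16 / 31, 7 / 31, 8 / 31], atol=1e-15
        )

    def test_distribution_five_tuples(self):
        d = distribution(WORKED_CODED, PNH).reshape(3, 5)
        np.testing.assert_allclose(d[0], [0.06, 0.24, 0.44, 0.64, 1.00], atol=1e-15)  # P
        np.testing.assert_allclose(d[1], [0.04, 0.28, 0.54, 0.78, 0.98], atol=1e-15)  # N
        np.testing.assert_allclose(d[2], [0.02, 0.20, 0.36, 0.74, 0.92], atol=1e-15)  # H

    def test_full_21_component_block(self, worked_record):
        block = ctd_block(worked_record, HYDROPHOBICITY)
        expected = np.array(
            [0.48, 0.32, 0.20]
            + [16 / 31, 7 / 31, 8 / 31]
            + [0.06, 0.24, 0.44, 0.64, 1.00]
            + [0.04, 0.28, 0.54, 0.78, 0.98]
            + [0.02, 0.20, 0.36, 0.74, 0.92]
        )
        np.testing.assert_allclose(block, expected, atol=1e-15)

    def test_aac_sums_to_one_with_counted_e_fraction(self, worked_record):
        aac = aac_vector(worked_record)
        assert aac.sum() == pytest.approx(1.0)
        # independent count of E in the printed sequence: 8 occurrences
        assert WORKED_SEQUENCE.count("E") == 8
        assert aac[AAC_ORDER.index("E")] == pytest.approx(8 / 50)


# ---------------------------------------------------------------------------
# operations on constructed inputs

@pytest.mark.parametrize(
    "seq,expected",
    [("GGGG", "NNNN"), ("RC", "PH")],
)
def test_encode_simple(seq, expected):
    assert encode_sequence(ProteinRecord("x", seq), HYDROPHOBICITY) == expected


def test_encode_missing_track_rejected():
    rec = ProteinRecord("x", "ACDE")
    with pytest.raises(EncodingError, match="ss"):
        encode_sequence(rec, GROUPINGS["secondary_structure"])


def test_record_rejects_nonstandard_residue_naming_position():
    with pytest.raises(SequenceError, match="position 3"):
        ProteinRecord("x", "ACXDE")


def test_sanitize_drops_nonstandard_and_aligns_tracks():
    rec = make_record("x", "ACXDE", ss_track="HHCCC", acc_track="HEHEH", sanitize=True)
    assert rec.sequence == "ACDE"
    assert rec.ss_track == "HHCC"
    assert rec.acc_track == "HEEH"


@pytest.mark.parametrize(
    "coded,expected",
    [
        ("NNNN", (0.0, 1.0, 0.0)),
        ("PH", (0.5, 0.0, 0.5)),
    ],
)
def test_composition_simple(coded, expected):
    np.testing.assert_allclose(composition(coded, PNH), expected)


def test_transition_no_transitions_is_zero_block():
    np.testing.assert_array_equal(transition("NNNN", PNH), [0.0, 0.0, 0.0])


def test_transition_single_pair():
    np.testing.assert_allclose(transition("PNPNP", PNH), [1.0, 0.0, 0.0])


def test_distribution_quantile_rule_on_four_letter_string():
    d = distribution("PPPP", PNH).reshape(3, 5)
    np.testing.assert_allclose(d[0], [0.25, 0.25, 0.50, 0.75, 1.00])
    np.testing.assert_array_equal(d[1], np.zeros(5))
    np.testing.assert_array_equal(d[2], np.zeros(5))


@pytest.mark.parametrize("fn", [composition, transition, distribution])
def test_empty_coded_string_rejected(fn):
    with pytest.raises(EncodingError):
        fn("", PNH)


def test_ctd_block_homogeneous_sequence():
    block = ctd_block(ProteinRecord("x", "GGGG"), HYDROPHOBICITY)
    expected = np.zeros(21)
    expected[1] = 1.0  # composition of N
    expected[11:16] = [0.25, 0.25, 0.50, 0.75, 1.00]  # distribution of N
    np.testing.assert_allclose(block, expected)


def test_accessibility_block_has_seven_components():
    rec = ProteinRecord("x", "ACDEFG", acc_track="HEHEHE")
    block = ctd_block(rec, SOLVENT_ACCESSIBILITY)
    assert block.shape == (7,)
    assert block[0] == pytest.approx(0.5)  # composition of hidden
    assert block[1] == pytest.approx(1.0)  # every adjacent pair differs


def test_aac_single_residue_and_pair():
    np.testing.assert_allclose(
        aac_vector(ProteinRecord("x", "AAAA")),
        np.eye(20)[AAC_ORDER.index("A")],
    )
    rk = aac_vector(ProteinRecord("x", "RK"))
    assert rk[AAC_ORDER.index("R")] == rk[AAC_ORDER.index("K")] == 0.5


class TestBiochemicalVector:
    def test_length_and_determinism(self, worked_record):
        ss, acc = propensity_tracks(worked_record.sequence)
        rec = ProteinRecord("x", worked_record.sequence, ss_track=ss, acc_track=acc)
        v1, v2 = biochemical_vector(rec), biochemical_vector(rec)
        assert v1.shape == (132,)
        np.testing.assert_array_equal(v1, v2)
        assert len(biochemical_feature_names()) == 132

    def test_worked_components_lead_the_vector(self, worked_record):
        v = biochemical_vector(worked_record, annotate=True)
        np.testing.assert_allclose(v[:3], [0.48, 0.32, 0.20], atol=1e-15)

    def test_missing_track_without_standin_rejected(self, worked_record):
        with pytest.raises(EncodingError):
            biochemical_vector(worked_record)


# ---------------------------------------------------------------------------
# randomized oracle agreement & properties

@pytest.mark.parametrize("seed", range(10))
def test_ctd_block_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 60))
    seq = "".join(rng.choice(list(AMINO_ACIDS), n))
    for grouping in (HYDROPHOBICITY, GROUPINGS["polarity"], GROUPINGS["polarizability"],
                     GROUPINGS["van_der_waals_volume"]):
        coded = encode_sequence(ProteinRecord("x", seq), grouping)
        comp, tran, dist = oracle_ctd(coded, grouping.categories)
        expected = np.array([float(v) for v in comp + tran + dist])
        np.testing.assert_allclose(
            ctd_block(ProteinRecord("x", seq), grouping), expected, atol=1e-12
        )


coded_strings = st.text(alphabet="PNH", min_size=1, max_size=80)


@settings(derandomize=True, max_examples=150)
@given(coded_strings)
def test_composition_sums_to_one(coded):
    assert composition(coded, PNH).sum() == pytest.approx(1.0)


@settings(derandomize=True, max_examples=150)
@given(coded_strings)
def test_transition_normalization(coded):
    t = transition(coded, PNH)
    has_diff = any(a != b for a, b in zip(coded, coded[1:]))
    if has_diff:
        assert t.sum() == pytest.approx(1.0)
    else:
        assert (t == 0).all()


@settings(derandomize=True, max_examples=150)
@given(coded_strings)
def test_distribution_monotone_and_endpoints(coded):
    d = distribution(coded, PNH).reshape(3, 5)
    n = len(coded)
    for ci, cat in enumerate(PNH):
        row = d[ci]
        assert (np.diff(row) >= -1e-15).all()
        assert ((0 <= row) & (row <= 1)).all()
        if cat in coded:
            last = max(i + 1 for i, c in enumerate(coded) if c == cat)
            assert row[4] == pytest.approx(last / n)
            # reversal duality: first occurrence of reversed = mirrored last
            rev = distribution(coded[::-1], PNH).reshape(3, 5)
            assert rev[ci][0] == pytest.approx((n - last + 1) / n)
        else:
            assert (row == 0).all()
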