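"""Glutamine window profiles, polyQ tract detection and classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyqmod.seqscan import (
    PolyQTract,
    ProteinRecord,
    aligned_q_profiles,
    classify_sequence,
    find_polyq_tracts,
    q_window_profile,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_tracts(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal Q runs by grouping consecutive identical letters."""
    out = []
    pos = 0
    for letter, grp in itertools.groupby(seq.upper()):
        n = len(list(grp))
        if letter == "Q" and n >= min_len:
            out.append((pos, pos + n))
        pos += n
    return out


def brute_force_q_rich(seq: str) -> bool:
    """Any substring of length >= 10 with strictly more than 50% Q."""
    q = np.array([c == "Q" for c in seq.upper()], dtype=int)
    prefix = np.concatenate([[0], np.cumsum(q)])
    n = len(seq)
    for length in range(10, n + 1):
        counts = prefix[length:] - prefix[:-length]
        if np.any(2 * counts > length):
            return True
    return False


def brute_force_polyq(seq: str) -> bool:
    return any(end - start >= 11 for start, end in brute_force_tracts(seq, 1))


def random_q_sequence(rng: np.random.Generator, length: int, q_prob: float) -> str:
    letters = np.where(rng.random(length) < q_prob, "Q", "A")
    return "".join(letters)


# ---------------------------------------------------------------------------
# q_window_profile
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sequence, expected_q, expected_run",
    [
        ("Q" * 50, 1.0, 1.0),
        ("A" * 50, 0.0, 0.0),
        # one run of 6 Qs plus 4 isolated Qs in 50 residues
        ("QQQQQQ" + "A" * 36 + "QAQAQAQA", 0.20, 0.12),
    ],
)
def test_single_window_fractions(sequence, expected_q, expected_run):
    prof = q_window_profile(ProteinRecord("p", sequence), window=50, run_min=5)
    assert prof.q_fraction.tolist() == [pytest.approx(expected_q)]
    assert prof.run_q_fraction.tolist() == [pytest.approx(expected_run)]


def test_short_sequence_yields_single_window():
    prof = q_window_profile(ProteinRecord("p", "QAQAQ"), window=50)
    assert len(prof.positions) == 1
    assert prof.window_size == 5
    assert prof.q_fraction[0] == pytest.approx(3 / 5)


def test_window_count_and_step():
    prof = q_window_profile(ProteinRecord("p", "A" * 120), window=50)
    assert prof.positions.tolist() == list(range(71))


def test_run_membership_is_decided_on_full_sequence():
    # the run straddles a window boundary: residues inside the window that
    # belong to the full-sequence run still count
    seq = "A" * 8 + "QQQQQQ" + "A" * 8
    prof = q_window_profile(ProteinRecord("p", seq), window=10, run_min=5)
    # window starting at 6 contains run residues 8..13 (6 of them)
    assert prof.run_q_fraction[6] == pytest.approx(6 / 10)
    # window 0 contains run residues 8,9 only
    assert prof.run_q_fraction[0] == pytest.approx(2 / 10)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        ProteinRecord("p", "")


def test_invalid_residue_rejected():
    with pytest.raises(ValueError, match="invalid residue"):
        ProteinRecord("p", "ACDB")


# ---------------------------------------------------------------------------
# find_polyq_tracts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sequence, min_len, expected",
    [
        ("AQQQQQQA", 6, [(1, 7)]),
        ("ACDEFG", 1, []),
        ("QQQAQQQQ", 3, [(0, 3), (4, 8)]),
        ("QQQQQ", 5, [(0, 5)]),
    ],
)
def test_tract_examples(sequence, min_len, expected):
    tracts = find_polyq_tracts(ProteinRecord("p", sequence), min_len=min_len)
    assert [(t.start, t.end) for t in tracts] == expected
    assert all(t.length == t.end - t.start for t in tracts)


def test_tracts_match_brute_force_on_random_sequences():
    rng = np.random.default_rng(101)
    for _ in range(200):
        seq = random_q_sequence(rng, 200, 0.4)
        got = find_polyq_tracts(ProteinRecord("p", seq), min_len=3)
        assert [(t.start, t.end) for t in got] == brute_force_tracts(seq, 3)


def test_tracts_case_insensitive():
    lower = find_polyq_tracts(ProteinRecord("p", "aqqqqqqa"), min_len=6)
    upper = find_polyq_tracts(ProteinRecord("p", "AQQQQQQA"), min_len=6)
    assert lower == upper


# ---------------------------------------------------------------------------
# classify_sequence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sequence, polyq, q_rich",
    [
        ("A" * 20 + "Q" * 11 + "A" * 20, True, True),  # >10 consecutive Qs
        ("A" * 20 + "Q" * 10 + "A" * 20, False, True),  # exactly 10: not polyQ
        ("AAAA" + "QAQAQQAQAQ" + "AAAA", False, True),  # 6 Q in 10 residues
        ("AAAA" + "QAQAQAQAQA" + "AAAA", False, False),  # 5 Q in 10: not > 50%
        ("ACDEFGHIKLMNPRSTVWY" * 3, False, False),
    ],
)
def test_classification_rules(sequence, polyq, q_rich):
    cls = classify_sequence(ProteinRecord("p", sequence))
    assert cls.is_polyq_protein is polyq
    assert cls.is_q_rich is q_rich


def test_classification_evidence_region_is_valid():
    cls = classify_sequence(ProteinRecord("p", "A" * 30 + "QQQAQQQAQQQ" + "A" * 30))
    assert cls.is_q_rich
    start, end = cls.evidence_region
    assert end - start >= 10
    stretch = ("A" * 30 + "QQQAQQQAQQQ" + "A" * 30)[start:end]
    assert stretch.count("Q") * 2 > len(stretch)


def test_classifier_agrees_with_brute_force():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        length = int(rng.integers(10, 300))
        seq = random_q_sequence(rng, length, float(rng.uniform(0.2, 0.6)))
        cls = classify_sequence(ProteinRecord("p", seq))
        assert cls.is_q_rich == brute_force_q_rich(seq), seq
        assert cls.is_polyq_protein == brute_force_polyq(seq), seq


@given(st.text(alphabet="AQLE", min_size=1, max_size=120))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_run_fraction_never_exceeds_q_fraction(seq):
    prof = q_window_profile(ProteinRecord("p", seq), window=50)
    assert np.all(prof.run_q_fraction <= prof.q_fraction + 1e-12)


@given(st.text(alphabet="ACDQ", min_size=1, max_size=80), st.integers(0, 80))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_inserting_q_never_decreases_max_window_fraction(seq, pos):
    pos = min(pos, len(seq))
    before = q_window_profile(ProteinRecord("p", seq), window=20).q_fraction.max()
    augmented = seq[:pos] + "Q" + seq[pos:]
    after = q_window_profile(ProteinRecord("p", augmented), window=20).q_fraction.max()
    assert after >= before - 1e-12


# ---------------------------------------------------------------------------
# aligned_q_profiles
# ---------------------------------------------------------------------------


def test_ungapped_alignment_reduces_to_plain_profile():
    seqs = ["QAQAQQAQAQ" * 6, "AAQQAAQQAA" * 6]
    aligned = [ProteinRecord(f"s{i}", s, aligned=True) for i, s in enumerate(seqs)]
    plain = [q_window_profile(ProteinRecord(f"s{i}", s)) for i, s in enumerate(seqs)]
    profs = aligned_q_profiles(aligned, window=50)
    for got, want in zip(profs, plain):
        np.testing.assert_allclose(got.q_fraction, want.q_fraction)
        np.testing.assert_allclose(got.run_q_fraction, want.run_q_fraction)


def test_all_gap_window_is_missing():
    aligned = [
        ProteinRecord("a", "-" * 10 + "QQQQQQQQQQ", aligned=True),
        ProteinRecord("b", "AAAAAAAAAA" + "QQQQQQQQQQ", aligned=True),
    ]
    profs = aligned_q_profiles(aligned, window=10)
    assert np.isnan(profs[0].q_fraction[0])
    assert profs[1].q_fraction[0] == pytest.approx(0.0)


def test_gap_does_not_interrupt_polyq_run():
    # four Qs, a gap column, three Qs: one run of 7 in the real sequence
    rec = ProteinRecord("a", "QQQQ-QQQ", aligned=True)
    profs = aligned_q_profiles([rec], window=8, run_min=5)
    # 7 run residues among 7 non-gap residues
    assert profs[0].run_q_fraction[0] == pytest.approx(1.0)


def test_gapped_profiles_match_direct_recount():
    rng = np.random.default_rng(99)
    letters = np.array(list("QA-"))
    seqs = ["".join(rng.choice(letters, p=[0.3, 0.5, 0.2], size=80)) for _ in range(5)]
    aligned = [ProteinRecord(f"s{i}", s, aligned=True) for i, s in enumerate(seqs)]
    profs = aligned_q_profiles(aligned, window=25)
    for rec, prof in zip(aligned, profs):
        for k, start in enumerate(prof.positions):
            window = rec.sequence[start : start + 25]
            residues = [c for c in window if c != "-"]
            if not residues:
                assert np.isnan(prof.q_fraction[k])
            else:
                want = sum(c == "Q" for c in residues) / len(residues)
                assert prof.q_fraction[k] == pytest.approx(want)


def test_ragged_alignment_rejected():
    with pytest.raises(ValueError, match="ragged"):
        aligned_q_profiles(
            [
                ProteinRecord("a", "QQQA", aligned=True),
                ProteinRecord("b", "QQQ", aligned=True),
            ]
        )
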