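"""Glutamine-content profiling and polyQ tract detection.

Polyglutamine (polyQ) expansions drive a family of neurodegenerative
diseases (Huntington's disease, the spinocerebellar ataxias), and proteins
carrying glutamine-rich regions are recurrent modifiers of polyQ toxicity.
This module implements the windowed glutamine scans used to characterise
such proteins:

* a sliding 50-residue window recording the fraction of glutamines and the
  fraction of residues lying in uninterrupted polyQ runs,
* detection of maximal uninterrupted glutamine tracts,
* the two standard sequence classes: a *polyQ protein* carries a run of
  more than 10 consecutive Qs; a *Q-rich protein* carries a stretch of at
  least 10 residues that is more than 50% glutamine,
* gap-aware window profiles over a multiple sequence alignment, so the
  conservation of Q-rich regions across orthologues can be compared on a
  common column coordinate.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinRecord",
    "QProfile",
    "PolyQTract",
    "SeqClassification",
    "q_window_profile",
    "find_polyq_tracts",
    "classify_sequence",
    "aligned_q_profiles",
]

# 20 standard residues plus X (unknown) and U (selenocysteine).
ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXU")
GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, case-normalised to upper case.

    ``aligned=True`` permits the gap character ``-`` (alignment rows).
    """

    id: str
    sequence: str
    aligned: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError(f"{self.id!r}: empty sequence")
        allowed = ALPHABET | {GAP} if self.aligned else ALPHABET
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"{self.id!r}: invalid residue(s) {sorted(bad)!r}; "
                f"allowed alphabet is the 20 amino acids plus X/U"
                + (" and '-'" if self.aligned else "")
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass(frozen=True)
class PolyQTract:
    """A maximal uninterrupted run of glutamines, 0-based half-open."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class QProfile:
    """Sliding-window glutamine content along one protein.

    ``q_fraction[i]`` is the fraction of glutamines among the (non-gap)
    residues of the window starting at ``positions[i]``;
    ``run_q_fraction[i]`` is the fraction of window residues lying inside
    uninterrupted Q runs longer than ``run_min``.  Windows with no scorable
    residue (all gaps) carry NaN.
    """

    protein_id: str
    window_size: int
    positions: np.ndarray
    q_fraction: np.ndarray
    run_q_fraction: np.ndarray
    run_min: int = 5

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.q_fraction = np.asarray(self.q_fraction, dtype=float)
        self.run_q_fraction = np.asarray(self.run_q_fraction, dtype=float)
        if not (len(self.positions) == len(self.q_fraction) == len(self.run_q_fraction)):
            raise ValueError("profile arrays must have equal length")


@dataclass
class SeqClassification:
    """Q-based classification of one protein."""

    protein_id: str
    is_polyq_protein: bool
    is_q_rich: bool
    tracts: list[PolyQTract] = field(default_factory=list)
    evidence_region: tuple[int, int] | None = None


def _q_mask(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8) == ord("Q")


def _run_mask(sequence: str, run_min: int) -> np.ndarray:
    """Boolean mask of residues in maximal Q runs of length > run_min."""
    mask = np.zeros(len(sequence), dtype=bool)
    for tract in find_polyq_tracts_str(sequence, min_len=run_min + 1):
        mask[tract.start : tract.end] = True
    return mask


def find_polyq_tracts_str(sequence: str, min_len: int = 6) -> list[PolyQTract]:
    """Maximal uninterrupted Q runs of length >= ``min_len`` in a raw string."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = sequence.upper()
    tracts: list[PolyQTract] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "Q":
            j = i
            while j < n and seq[j] == "Q":
                j += 1
            if j - i >= min_len:
                tracts.append(PolyQTract(i, j))
            i = j
        else:
            i += 1
    return tracts


def find_polyq_tracts(protein: ProteinRecord, min_len: int = 6) -> list[PolyQTract]:
    """All maximal uninterrupted polyQ tracts of length >= ``min_len``.

    The default ``min_len=6`` selects runs of more than 5 consecutive
    glutamines, the cut-off used for short polyQ tracts in modifier
    proteins.
    """
    return find_polyq_tracts_str(protein.sequence, min_len=min_len)


def q_window_profile(
    protein: ProteinRecord, window: int = 50, run_min: int = 5
) -> QProfile:
    """Sliding-window glutamine profile with step 1.

    One window per full start position ``0 .. L-window``; a sequence
    shorter than the window yields a single window covering it entirely.
    Run membership (uninterrupted Q runs of length > ``run_min``) is
    decided on the full sequence first and then counted inside each
    window, so profiles are continuous along the protein.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = protein.sequence
    L = len(seq)
    w = min(window, L)
    qm = _q_mask(seq).astype(float)
    rm = _run_mask(seq, run_min).astype(float)
    kernel = np.ones(w)
    q_counts = np.convolve(qm, kernel, mode="valid")
    r_counts = np.convolve(rm, kernel, mode="valid")
    positions = np.arange(L - w + 1)
    return QProfile(
        protein_id=protein.id,
        window_size=w,
        positions=positions,
        q_fraction=q_counts / w,
        run_q_fraction=r_counts / w,
        run_min=run_min,
    )


def classify_sequence(protein: ProteinRecord) -> SeqClassification:
    """Classify a protein as polyQ and/or Q-rich.

    polyQ protein: contains a stretch of more than 10 consecutive Qs
    (i.e. a maximal run of length >= 11).  Q-rich protein: contains a
    stretch of at least 10 residues with strictly more than 50% Qs.

    The Q-rich search is exact over all substrings of length >= 10: with
    residue scores +1 for Q and -1 otherwise, a qualifying stretch exists
    iff some substring of length >= 10 has positive score, found in O(L)
    with prefix sums and a running minimum.
    """
    seq = protein.sequence
    tracts = find_polyq_tracts_str(seq, min_len=6)
    is_polyq = any(t.length >= 11 for t in tracts)

    score = np.where(_q_mask(seq), 1, -1)
    prefix = np.concatenate([[0], np.cumsum(score)])
    evidence: tuple[int, int] | None = None
    best = 0
    min_idx = 0  # argmin of prefix[0..j-10]
    for j in range(10, len(seq) + 1):
        i = j - 10
        if prefix[i] < prefix[min_idx]:
            min_idx = i
        gain = prefix[j] - prefix[min_idx]
        if gain > best:
            best = gain
            evidence = (min_idx, j)
    return SeqClassification(
        protein_id=protein.id,
        is_polyq_protein=is_polyq,
        is_q_rich=evidence is not None,
        tracts=tracts,
        evidence_region=evidence,
    )


def aligned_q_profiles(
    alignment: list[ProteinRecord], window: int = 50, run_min: int = 5
) -> list[QProfile]:
    """Per-sequence Q profiles on a common alignment-column coordinate.

    Window denominators count only non-gap residues; a window containing
    no residue of a sequence yields NaN for that sequence.  Run
    membership is decided on the ungapped sequence (alignment gaps do not
    interrupt a polyQ run) and mapped back to columns.
    """
    if not alignment:
        return []
    L = len(alignment[0].sequence)
    for rec in alignment:
        if len(rec.sequence) != L:
            raise ValueError(
                f"ragged alignment: {rec.id!r} has length {len(rec.sequence)}, expected {L}"
            )
    w = min(window, L)
    kernel = np.ones(w)
    positions = np.arange(L - w + 1)
    profiles: list[QProfile] = []
    for rec in alignment:
        seq = rec.sequence
        chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        nongap = (chars != ord(GAP)).astype(float)
        qm = (chars == ord("Q")).astype(float)
        # map ungapped run membership back onto columns
        ungapped = seq.replace(GAP, "")
        run_cols = np.zeros(L, dtype=float)
        if ungapped:
            rm = _run_mask(ungapped, run_min)
            run_cols[nongap.astype(bool)] = rm.astype(float)
        denom = np.convolve(nongap, kernel, mode="valid")
        q_counts = np.convolve(qm, kernel, mode="valid")
        r_counts = np.convolve(run_cols, kernel, mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            q_frac = np.where(denom > 0, q_counts / denom, np.nan)
            r_frac = np.where(denom > 0, r_counts / denom, np.nan)
        profiles.append(
            QProfile(
                protein_id=rec.id,
                window_size=w,
                positions=positions,
                q_fraction=q_frac,
                run_q_fraction=r_frac,
                run_min=run_min,
            )
        )
    return profiles
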