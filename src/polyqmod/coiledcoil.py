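"""Sliding-window heptad-propensity coiled-coil prediction.

Coiled coils are alpha-helical oligomerisation motifs built on a 7-residue
(heptad, positions a-g) repeat with hydrophobic residues at positions a
and d.  They can be detected from sequence alone by scoring each window of
a protein against a table of per-position residue propensities and
converting the score to a probability by comparing it with the score
distributions of known coiled-coil and globular sequence.

The scan implemented here follows the classical windowed-propensity
scheme: for every window placement and each of the 7 possible heptad
registers, the window score is the (optionally a/d-weighted) geometric
mean of the residue propensities; each residue keeps the best score of
any window/register covering it; the score is mapped to a probability

    P(cc | s) = G(s; m_cc, sd_cc) / (G(s; m_cc, sd_cc) + r * G(s; m_g, sd_g))

where ``G`` is a Gaussian density, the means/sds come from the matrix
calibration block for the chosen window size, and ``r`` is the prior odds
of globular over coiled-coil sequence (default 30).

The propensity table and its calibration constants are shipped as a TSV
data asset (see :func:`load_default_matrix`); both are pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

from .seqscan import ProteinRecord

__all__ = [
    "PropensityMatrix",
    "Calibration",
    "CCPrediction",
    "CCSegment",
    "load_default_matrix",
    "cc_scan",
    "cc_segments",
    "has_cc",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HEPTAD = "abcdefg"


@dataclass(frozen=True)
class Calibration:
    """Score-distribution constants for one (window, weighted) setting."""

    mean_cc: float
    sd_cc: float
    mean_glob: float
    sd_glob: float
    prior_ratio: float = 30.0

    def __post_init__(self) -> None:
        if self.sd_cc <= 0 or self.sd_glob <= 0:
            raise ValueError("calibration sds must be positive")
        if self.prior_ratio <= 0:
            raise ValueError("prior_ratio must be positive")

    def probability(self, score: np.ndarray) -> np.ndarray:
        g_cc = norm.pdf(score, self.mean_cc, self.sd_cc)
        g_gl = norm.pdf(score, self.mean_glob, self.sd_glob)
        denom = g_cc + self.prior_ratio * g_gl
        with np.errstate(invalid="ignore"):
            p = np.where(denom > 0, g_cc / denom, float(self.mean_cc > self.mean_glob))
        return p


class PropensityMatrix:
    """20 x 7 heptad propensity table plus per-window calibration.

    ``propensity[aa][pos]`` must be positive; ``ad_weight`` is the extra
    weight applied to the hydrophobic-core positions a and d in weighted
    scans.  Ambiguity codes X and U score the column-wise geometric mean
    of the 20 standard residues (neutral under geometric averaging).
    """

    def __init__(
        self,
        name: str,
        propensity: dict[str, "list[float] | np.ndarray"],
        calibration: dict[tuple[int, bool], Calibration],
        ad_weight: float = 2.5,
    ) -> None:
        self.name = name
        self.ad_weight = float(ad_weight)
        if self.ad_weight <= 0:
            raise ValueError("ad_weight must be positive")
        table = np.zeros((len(AA20), 7))
        for i, aa in enumerate(AA20):
            if aa not in propensity:
                raise ValueError(f"matrix {name!r} is missing residue {aa!r}")
            row = np.asarray(propensity[aa], dtype=float)
            if row.shape != (7,):
                raise ValueError(f"residue {aa!r}: expected 7 heptad propensities")
            if np.any(row <= 0):
                raise ValueError(f"residue {aa!r}: propensities must be positive")
            table[i] = row
        self._table = table
        # geometric-mean column for X/U
        self._ambiguous = np.exp(np.log(table).mean(axis=0))
        self.calibration = dict(calibration)

    def row(self, aa: str) -> np.ndarray:
        """Propensities (length 7, positions a..g) for one residue."""
        if aa in ("X", "U"):
            return self._ambiguous
        i = AA20.find(aa)
        if i < 0:
            raise ValueError(f"no propensity entry for residue {aa!r}")
        return self._table[i]

    def calibration_for(self, window: int, weighted: bool) -> Calibration:
        try:
            return self.calibration[(window, weighted)]
        except KeyError:
            raise ValueError(
                f"matrix {self.name!r} has no calibration for "
                f"window={window}, weighted={weighted}"
            ) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityMatrix":
        """Load a matrix from the shipped TSV layout.

        The file holds key/value header lines (``name``, ``ad_weight``),
        a ``[propensity]`` block of 20 rows x 7 columns and a
        ``[calibration]`` block keyed by (window, weighted).
        """
        name = "unnamed"
        ad_weight = 2.5
        propensity: dict[str, list[float]] = {}
        calibration: dict[tuple[int, bool], Calibration] = {}
        section = None
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            fields = line.split("\t")
            if section is None:
                if fields[0] == "name":
                    name = fields[1]
                elif fields[0] == "ad_weight":
                    ad_weight = float(fields[1])
            elif section == "propensity":
                if fields[0] == "aa":
                    continue
                propensity[fields[0]] = [float(x) for x in fields[1:8]]
            elif section == "calibration":
                if fields[0] == "window":
                    continue
                window, weighted = int(fields[0]), bool(int(fields[1]))
                calibration[(window, weighted)] = Calibration(
                    mean_cc=float(fields[2]),
                    sd_cc=float(fields[3]),
                    mean_glob=float(fields[4]),
                    sd_glob=float(fields[5]),
                    prior_ratio=float(fields[6]),
                )
        return cls(name, propensity, calibration, ad_weight)


def load_default_matrix() -> PropensityMatrix:
    """The packaged default propensity matrix (MTIDK-style residue
    propensities; calibration constants derived by simulation, see
    docs/methods.md)."""
    ref = resources.files("polyqmod") / "data" / "coils_matrix.tsv"
    with resources.as_file(ref) as path:
        return PropensityMatrix.from_tsv(path)


@dataclass
class CCPrediction:
    """Per-residue coiled-coil scores, probabilities and best register."""

    protein_id: str
    window_size: int
    score: np.ndarray
    probability: np.ndarray
    frame: np.ndarray  # heptad letter a..g of each residue in its best window

    @property
    def max_probability(self) -> float:
        return float(self.probability.max())


@dataclass(frozen=True)
class CCSegment:
    """Maximal run of residues at or above the probability threshold."""

    start: int
    end: int
    max_probability: float
    mean_probability: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _log_propensities(
    sequence: str, matrix: PropensityMatrix
) -> np.ndarray:
    """log propensity of residue i at heptad position p; shape (L, 7)."""
    out = np.empty((len(sequence), 7))
    for i, aa in enumerate(sequence):
        out[i] = np.log(matrix.row(aa))
    return out


def cc_scan(
    protein: ProteinRecord,
    matrix: PropensityMatrix | None = None,
    window: int = 28,
    weighted: bool = False,
) -> CCPrediction:
    """Score a protein for coiled-coil propensity.

    For each of the 7 heptad registers ``f`` residue ``i`` occupies heptad
    position ``(i + f) mod 7``; the score of the window starting at ``s``
    is the weighted geometric mean of the propensities of its residues,
    with weight ``ad_weight`` on positions a/d when ``weighted``.  Each
    residue takes the best score over all windows and registers covering
    it; probabilities follow from the matrix calibration for ``window``.
    """
    if matrix is None:
        matrix = load_default_matrix()
    calib = matrix.calibration_for(window, weighted)
    seq = protein.sequence
    L = len(seq)
    if L < window:
        raise ValueError(
            f"{protein.id!r}: sequence length {L} is shorter than window {window}"
        )
    logp = _log_propensities(seq, matrix)  # (L, 7)

    pos_weights = np.ones(7)
    if weighted:
        pos_weights[[0, 3]] = matrix.ad_weight

    n_windows = L - window + 1
    best_score = np.full(L, -np.inf)
    best_frame = np.zeros(L, dtype=int)
    idx = np.arange(L)
    for f in range(7):
        hpos = (idx + f) % 7
        wlog = logp[idx, hpos] * pos_weights[hpos]
        wts = pos_weights[hpos]
        csum = np.concatenate([[0.0], np.cumsum(wlog)])
        cw = np.concatenate([[0.0], np.cumsum(wts)])
        win_log = csum[window:] - csum[:-window]  # (n_windows,)
        win_w = cw[window:] - cw[:-window]
        win_score = np.exp(win_log / win_w)
        # residue i is covered by windows starting in [i-window+1, i]
        padded = np.full(L, -np.inf)
        padded[:n_windows] = win_score
        ext = np.concatenate([np.full(window - 1, -np.inf), padded])
        res_best = sliding_window_view(ext, window).max(axis=1)
        better = res_best > best_score
        best_score[better] = res_best[better]
        best_frame[better] = f
    heptad_pos = (idx + best_frame) % 7
    frame = np.array([HEPTAD[p] for p in heptad_pos])
    return CCPrediction(
        protein_id=protein.id,
        window_size=window,
        score=best_score,
        probability=calib.probability(best_score),
        frame=frame,
    )


def cc_segments(
    pred: CCPrediction, threshold: float = 0.8, min_len: int = 1
) -> list[CCSegment]:
    """Maximal runs of residues with probability >= threshold and length
    >= min_len."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    above = pred.probability >= threshold
    segments: list[CCSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_len:
                p = pred.probability[i:j]
                segments.append(CCSegment(i, j, float(p.max()), float(p.mean())))
            i = j
        else:
            i += 1
    return segments


def has_cc(
    protein: ProteinRecord,
    matrix: PropensityMatrix | None = None,
    window: int = 28,
    threshold: float = 0.8,
    weighted: bool = False,
) -> bool:
    """True iff any residue reaches the probability threshold."""
    pred = cc_scan(protein, matrix=matrix, window=window, weighted=weighted)
    return len(cc_segments(pred, threshold=threshold, min_len=1)) > 0
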