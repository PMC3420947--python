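"""Derive the calibration block of the shipped coiled-coil matrix.

The windowed-propensity score of a sequence window only becomes a
probability once it is compared with reference score distributions.  The
original screening tool shipped such constants with its matrix; this
package derives its own, by simulation, and freezes them into
``src/polyqmod/data/coils_matrix.tsv``:

* coiled-coil population: windows of ideal heptad repeats (LEELEKK) read
  in the correct register, with a 5% per-residue substitution rate to a
  background residue, emulating imperfect natural coiled coils;
* globular population: the same heptad sequence material shuffled, scored
  at the best of the 7 registers.  Using composition-matched but
  register-incoherent sequence as the null makes heptad periodicity, not
  residue composition, drive the probability.

Both distributions are summarised as Gaussians with a common (pooled)
standard deviation, which makes the posterior probability a logistic
function of the score and therefore provably monotone.  The prior odds of
globular over coiled-coil sequence is fixed at 30.

Run from the repository root:  python scripts/build_matrix_calibration.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from polyqmod.coiledcoil import PropensityMatrix  # noqa: E402
from polyqmod.synthetic import HEPTAD_IDEAL, SWISSPROT_FREQS  # noqa: E402

MATRIX_PATH = Path(__file__).resolve().parents[1] / "src/polyqmod/data/coils_matrix.tsv"
WINDOWS = (14, 21, 28)
PRIOR_RATIO = 30.0
SUBSTITUTION_RATE = 0.05
N_CC = 20_000
N_SHUFFLED_SEQS = 2_000
SEED = 20120901


def window_scores(seq: str, matrix: PropensityMatrix, window: int, weighted: bool) -> np.ndarray:
    """Best-of-7-registers score for every window placement (direct form)."""
    pos_weights = np.ones(7)
    if weighted:
        pos_weights[[0, 3]] = matrix.ad_weight
    logp = np.array([np.log(matrix.row(aa)) for aa in seq])
    n = len(seq) - window + 1
    out = np.empty(n)
    idx = np.arange(len(seq))
    best = np.full(n, -np.inf)
    for f in range(7):
        hpos = (idx + f) % 7
        wlog = logp[idx, hpos] * pos_weights[hpos]
        wts = pos_weights[hpos]
        c = np.concatenate([[0.0], np.cumsum(wlog)])
        cw = np.concatenate([[0.0], np.cumsum(wts)])
        s = np.exp((c[window:] - c[:-window]) / (cw[window:] - cw[:-window]))
        best = np.maximum(best, s)
    out[:] = best
    return out


def register_score(seq: str, matrix: PropensityMatrix, window: int, weighted: bool) -> float:
    """Score of the first window read in register 0 (positions a,b,c,...)."""
    pos_weights = np.ones(7)
    if weighted:
        pos_weights[[0, 3]] = matrix.ad_weight
    logs = []
    wts = []
    for i, aa in enumerate(seq[:window]):
        p = i % 7
        logs.append(np.log(matrix.row(aa)[p]) * pos_weights[p])
        wts.append(pos_weights[p])
    return float(np.exp(np.sum(logs) / np.sum(wts)))


def main() -> None:
    matrix = PropensityMatrix.from_tsv(MATRIX_PATH)
    rng = np.random.default_rng(SEED)
    letters = np.array(list(SWISSPROT_FREQS))
    freqs = np.array(list(SWISSPROT_FREQS.values()))
    freqs = freqs / freqs.sum()

    lines = []
    for window in WINDOWS:
        n_heptads = int(np.ceil(window / 7)) + 1
        base = (HEPTAD_IDEAL * n_heptads)
        for weighted in (False, True):
            # coiled-coil population: correct register, 5% substitutions
            cc_scores = np.empty(N_CC)
            for i in range(N_CC):
                chars = list(base[:window])
                hits = rng.random(window) < SUBSTITUTION_RATE
                for j in np.flatnonzero(hits):
                    chars[j] = rng.choice(letters, p=freqs)
                cc_scores[i] = register_score("".join(chars), matrix, window, weighted)
            # globular population: shuffled heptad material, best register
            glob_scores = []
            for _ in range(N_SHUFFLED_SEQS):
                chars = np.array(list(base * 2))
                rng.shuffle(chars)
                glob_scores.append(window_scores("".join(chars), matrix, window, weighted))
            glob_scores = np.concatenate(glob_scores)

            m_cc, s_cc = cc_scores.mean(), cc_scores.std(ddof=1)
            m_g, s_g = glob_scores.mean(), glob_scores.std(ddof=1)
            sd = float(np.sqrt(0.5 * (s_cc**2 + s_g**2)))  # pooled: monotone logistic
            lines.append(
                f"{window}\t{int(weighted)}\t{m_cc:.4f}\t{sd:.4f}\t{m_g:.4f}\t{sd:.4f}\t{PRIOR_RATIO:g}"
            )

            # diagnostics
            s_star = 0.5 * (m_cc + m_g) + sd**2 * np.log(4 * PRIOR_RATIO) / (m_cc - m_g)
            ideal = register_score(base[:window], matrix, window, weighted)
            bg = rng.choice(letters, size=400, p=freqs)
            bg_max = window_scores("".join(bg), matrix, window, weighted).max()
            print(
                f"w={window} weighted={weighted}: cc N({m_cc:.3f},{s_cc:.3f}) "
                f"glob N({m_g:.3f},{s_g:.3f}) pooled sd {sd:.3f} | "
                f"p=0.8 at score {s_star:.3f}; ideal {ideal:.3f}, "
                f"glob 99.9th {np.quantile(glob_scores, 0.999):.3f}, bg max {bg_max:.3f}"
            )

    text = MATRIX_PATH.read_text()
    head, _, tail = text.partition("window\tweighted\tmean_cc\tsd_cc\tmean_glob\tsd_glob\tprior_ratio\n")
    MATRIX_PATH.write_text(
        head
        + "window\tweighted\tmean_cc\tsd_cc\tmean_glob\tsd_glob\tprior_ratio\n"
        + "\n".join(lines)
        + "\n"
    )
    print(f"wrote {len(lines)} calibration rows to {MATRIX_PATH}")


if __name__ == "__main__":
    main()
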