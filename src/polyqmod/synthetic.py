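"""Seeded generators for every input the analysis stages consume.

The study's raw assay data are not deposited, so the package ships
generators that emulate each data stream's statistical structure:

* protein sequences with planted polyQ tracts, Q-rich stretches and ideal
  heptad coiled-coil segments on a Swiss-Prot-like residue background,
* caspase/densitometry plate tables for the overexpression screen —
  three independent experiments in triplicate, lognormal multiplicative
  noise around planted fold-effects, Poisson cell counts,
* LUMIER firefly/Renilla triplets with planted binding ratios,
* far-UV CD spectra as mixtures of secondary-structure basis spectra with
  additive Gaussian instrument noise,
* a Bernoulli proteome background for enrichment tests.

Every generator takes a single integer seed and derives an independent
stream from it (one spawn key per generator), so a run is reproducible
bit-for-bit while generators stay decoupled.  Truth tables accompany each
output so detectors can be scored against the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cdspec import RawSpectrum
from .enrichment import Background
from .seqscan import ProteinRecord

__all__ = [
    "SWISSPROT_FREQS",
    "HEPTAD_IDEAL",
    "gen_sequences",
    "gen_screen_plate",
    "gen_lumier",
    "gen_cd",
    "cd_basis",
    "gen_proteome",
    "load_modifier_table",
    "modifier_plate_from_table",
    "modifier_sequences_from_table",
]

# Approximate Swiss-Prot amino-acid composition (normalised at use).
SWISSPROT_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: One ideal heptad (positions a-g): leucine core at a/d, charged elsewhere.
HEPTAD_IDEAL = "LEELEKK"

# Fixed spawn keys: one independent stream per generator under one seed.
_STREAMS = {
    "sequences": 1,
    "plate": 2,
    "lumier": 3,
    "cd": 4,
    "proteome": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def _background(rng: np.random.Generator, length: int) -> np.ndarray:
    letters = np.array(list(SWISSPROT_FREQS))
    p = np.array(list(SWISSPROT_FREQS.values()))
    return rng.choice(letters, size=length, p=p / p.sum())


def gen_sequences(
    n: int | None = None,
    length: int = 400,
    planted: list[dict | None] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random protein sequences with optionally planted features.

    ``planted`` holds one spec per sequence (None for pure background);
    recognised keys: ``polyq_len`` (exact uninterrupted Q run length),
    ``heptad_repeats`` (count of ideal heptads planted contiguously) and
    ``q_rich_len`` (stretch of that length with ~60% Q, interrupted so it
    is Q-rich without long polyQ runs).  Features are placed left to right
    with background spacers; infeasible placements raise.  Returns the
    records plus a truth table with planted coordinates.
    """
    if planted is None:
        if n is None:
            raise ValueError("give n or planted")
        planted = [None] * n
    if n is None:
        n = len(planted)
    if len(planted) != n:
        raise ValueError("planted must have one entry per sequence")
    rng = _rng(seed, "sequences")
    records: list[ProteinRecord] = []
    truth_rows = []
    for i, spec in enumerate(planted):
        spec = dict(spec or {})
        seq = _background(rng, length)
        sid = spec.pop("id", f"syn{i:03d}")
        features: list[tuple[str, np.ndarray]] = []
        if "polyq_len" in spec:
            k = int(spec.pop("polyq_len"))
            features.append(("polyq", np.array(list("Q" * k))))
        if "heptad_repeats" in spec:
            r = int(spec.pop("heptad_repeats"))
            features.append(("heptad", np.array(list(HEPTAD_IDEAL * r))))
        if "q_rich_len" in spec:
            k = int(spec.pop("q_rich_len"))
            # ~60% Q but runs capped at 3: QQQA repeated
            stretch = ("QQQA" * ((k // 4) + 1))[:k]
            features.append(("q_rich", np.array(list(stretch))))
        if spec:
            raise ValueError(f"unknown planted key(s) {sorted(spec)}")
        total = sum(len(f[1]) for f in features)
        if total > length:
            raise ValueError(
                f"sequence {sid!r}: planted features ({total} aa) exceed length {length}"
            )
        # left-to-right placement with random gaps
        slack = length - total
        cuts = np.sort(rng.integers(0, slack + 1, size=len(features)))
        pos = 0
        for (kind, residues), cut in zip(features, cuts):
            start = int(cut) + pos
            seq[start : start + len(residues)] = residues
            # guard the flanks so planted polyQ runs stay exact
            if kind == "polyq":
                if start > 0 and seq[start - 1] == "Q":
                    seq[start - 1] = "A"
                if start + len(residues) < length and seq[start + len(residues)] == "Q":
                    seq[start + len(residues)] = "A"
            truth_rows.append(
                {
                    "id": sid,
                    "feature": kind,
                    "start": start,
                    "end": start + len(residues),
                }
            )
            pos = start + len(residues) - int(cut)
        records.append(ProteinRecord(sid, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["id", "feature", "start", "end"])
    return records, truth


def gen_screen_plate(
    effect_map: dict[str, tuple[float, float]] | None = None,
    n_modifiers: int | None = None,
    cv: float = 0.10,
    n_experiments: int = 3,
    n_replicates: int = 3,
    n_control_replicates: int = 12,
    alone_map: dict[str, float] | None = None,
    mean_cells: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic screen plate table with planted fold-effects.

    ``effect_map`` maps modifier -> (toxicity fold, aggregation fold)
    relative to the control (1.0 = no effect); with ``n_modifiers`` given
    instead, that many null modifiers are generated.  Caspase
    fluorescence per well is cell_count x baseline x fold x lognormal(cv)
    with the control baseline at 1.0 activity per cell; cell counts are
    Poisson(mean_cells); densitometry is 100 x fold x lognormal(cv).
    Modifier-alone control wells (fold from ``alone_map``, default 1.0)
    are included for the re-test exclusion rule.

    Every modifier on a plate is compared against the same control wells,
    so the control mean is a shared noise source; plate designs therefore
    dedicate more wells to the reference than to each condition.  The
    default is a 12-well control column per experiment against triplicate
    modifier wells.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if effect_map is None:
        if n_modifiers is None:
            raise ValueError("give effect_map or n_modifiers")
        effect_map = {f"mod{i:04d}": (1.0, 1.0) for i in range(n_modifiers)}
    alone_map = alone_map or {}
    rng = _rng(seed, "plate")
    sigma = np.sqrt(np.log(1 + cv**2)) if cv > 0 else 0.0

    def noise(size):
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    def cells(size):
        return np.maximum(1, rng.poisson(mean_cells, size=size))

    rows = []
    for exp in range(1, n_experiments + 1):
        for condition in ("with_reporter", "modifier_alone"):
            n_ctl = n_control_replicates
            cc = cells(n_ctl)
            fl = cc * 1.0 * noise(n_ctl)
            dens = 100.0 * noise(n_ctl) if condition == "with_reporter" else np.nan
            for rep in range(n_ctl):
                rows.append(
                    {
                        "experiment": exp,
                        "replicate": rep + 1,
                        "modifier": "CONTROL",
                        "condition": condition,
                        "fluorescence": fl[rep],
                        "cell_count": cc[rep],
                        "densitometry": dens[rep] if condition == "with_reporter" else np.nan,
                    }
                )
        for mod, (tox_fold, agg_fold) in effect_map.items():
            for condition in ("with_reporter", "modifier_alone"):
                fold = tox_fold if condition == "with_reporter" else alone_map.get(mod, 1.0)
                cc = cells(n_replicates)
                fl = cc * fold * noise(n_replicates)
                dens = 100.0 * agg_fold * noise(n_replicates)
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "experiment": exp,
                            "replicate": rep + 1,
                            "modifier": mod,
                            "condition": condition,
                            "fluorescence": fl[rep],
                            "cell_count": cc[rep],
                            "densitometry": dens[rep] if condition == "with_reporter" else np.nan,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {
                "modifier": m,
                "toxicity_fold": t,
                "aggregation_fold": a,
                "alone_fold": alone_map.get(m, 1.0),
            }
            for m, (t, a) in effect_map.items()
        ]
    )
    return table, truth


def gen_lumier(
    true_ratio_map: dict[tuple[str, str], float],
    cv: float = 0.10,
    n_replicates: int = 3,
    baseline: float = 100.0,
    renilla_ip: float = 1000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic LUMIER table with planted binding ratios.

    Control samples B and C share the firefly baseline; sample A reads
    baseline x true_ratio.  All readings carry lognormal noise of the
    given CV.  Renilla signals mark successful bait immunoprecipitation
    in samples A and C (bait present) and background in B.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = _rng(seed, "lumier")
    sigma = np.sqrt(np.log(1 + cv**2)) if cv > 0 else 0.0

    def noise(size):
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    rows = []
    for (bait, prey), ratio in true_ratio_map.items():
        means = {"A": baseline * ratio, "B": baseline, "C": baseline}
        renilla = {"A": renilla_ip, "B": 0.05 * renilla_ip, "C": renilla_ip}
        for sample in "ABC":
            fl = means[sample] * noise(n_replicates)
            rl = renilla[sample] * noise(n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "bait": bait,
                        "prey": prey,
                        "sample": sample,
                        "replicate": rep + 1,
                        "firefly": fl[rep],
                        "renilla": rl[rep],
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"bait": b, "prey": p, "true_ratio": r, "interacting": r > 1.5}
            for (b, p), r in true_ratio_map.items()
        ]
    )
    return table, truth


def cd_basis(wavelengths: np.ndarray) -> dict[str, np.ndarray]:
    """Secondary-structure basis spectra in MRE units on the given grid.

    Gaussian-band caricatures of the canonical far-UV shapes: the helix
    basis has |[theta]208| > |[theta]222| (ratio < 1), the coiled-coil
    basis has the 222 nm band deepened by helix packing (ratio > 1), the
    sheet basis a single ~218 nm minimum, the coil basis a deep ~198 nm
    minimum.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def band(center, width, amplitude):
        return amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)

    return {
        "helix": band(192, 5.5, 6.5e4) + band(208, 6.0, -3.6e4) + band(222, 6.5, -2.8e4),
        "coiled_coil": band(192, 5.5, 6.0e4) + band(208, 6.0, -2.8e4) + band(222, 6.5, -3.4e4),
        "sheet": band(196, 5.0, 3.0e4) + band(218, 7.0, -1.6e4),
        "coil": band(198, 6.0, -3.5e4) + band(220, 8.0, -2.0e3),
    }


def gen_cd(
    fractions: dict[str, float],
    noise_sd: float = 0.0,
    concentration: float = 5e-6,
    path_length: float = 0.1,
    n_residues: int = 100,
    wavelengths: np.ndarray | None = None,
    name: str = "synthetic",
    seed: int = 0,
) -> RawSpectrum:
    """Synthetic raw CD spectrum as a mixture of basis spectra.

    ``fractions`` over {helix, sheet, coil, coiled_coil} must sum to 1.
    The mixture MRE is scaled to machine millidegrees through the sample
    metadata and Gaussian noise of ``noise_sd`` mdeg is added.
    """
    if wavelengths is None:
        wavelengths = np.arange(250.0, 189.0, -1.0)  # 250 -> 190 nm at 1 nm
    total = sum(fractions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"fractions must sum to 1 (got {total})")
    basis = cd_basis(wavelengths)
    unknown = set(fractions) - set(basis)
    if unknown:
        raise ValueError(f"unknown basis component(s) {sorted(unknown)}")
    mre = np.zeros_like(np.asarray(wavelengths, dtype=float))
    for comp, frac in fractions.items():
        mre = mre + frac * basis[comp]
    mdeg = mre * 10.0 * path_length * concentration * n_residues
    if noise_sd > 0:
        rng = _rng(seed, "cd")
        mdeg = mdeg + rng.normal(0.0, noise_sd, size=mdeg.shape)
    return RawSpectrum(
        wavelengths=np.asarray(wavelengths, dtype=float),
        ellipticity=mdeg,
        concentration=concentration,
        path_length=path_length,
        n_residues=n_residues,
        name=name,
    )


def gen_proteome(
    n: int = 73_427, cc_fraction: float = 0.203, seed: int = 0
) -> tuple[Background, np.ndarray]:
    """Bernoulli coiled-coil flags for a synthetic proteome background."""
    if not 0 < cc_fraction < 1:
        raise ValueError("cc_fraction must be in (0, 1)")
    rng = _rng(seed, "proteome")
    flags = rng.random(n) < cc_fraction
    return Background(n_proteins=n, cc_fraction=cc_fraction), flags


# ---------------------------------------------------------------------------
# The 21-modifier reference table and its synthetic realisations
# ---------------------------------------------------------------------------

# Planted fold-effects realising each call class in synthetic plates.
CLASS_FOLDS = {"enhancer": 1.5, "suppressor": 0.55, "none": 1.0}
AGG_FOLDS = {"enhancer": 1.6, "suppressor": 0.5, "none": 1.0}


def load_modifier_table(path: str | Path | None = None) -> pd.DataFrame:
    """The 21-modifier reference table (classes, ATXN3/CC/Q flags).

    Reconstructed from the published per-protein screen results; ids not
    named per class in the text are synthetic placeholders.
    """
    if path is None:
        ref = resources.files("polyqmod") / "data" / "modifier_table_synthetic.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def modifier_plate_from_table(
    table: pd.DataFrame,
    cv: float = 0.05,
    effect_column: str = "toxicity_class",
    aggregation_column: str = "aggregation_class",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic screen plate realising the reference table's calls."""
    effect_map = {
        row["modifier"]: (
            CLASS_FOLDS[row[effect_column]],
            AGG_FOLDS[row[aggregation_column]],
        )
        for _, row in table.iterrows()
    }
    return gen_screen_plate(effect_map=effect_map, cv=cv, seed=seed)


def modifier_sequences_from_table(
    table: pd.DataFrame,
    length: int = 400,
    heptad_repeats: int = 8,
    polyq_len: int = 15,
    q_rich_len: int = 40,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Synthetic modifier sequences realising the table's CC/Q flags."""
    planted = []
    for _, row in table.iterrows():
        spec: dict = {"id": row["modifier"]}
        if row["has_cc"]:
            spec["heptad_repeats"] = heptad_repeats
        if row["polyq"]:
            spec["polyq_len"] = polyq_len
        elif row["q_rich"]:
            spec["q_rich_len"] = q_rich_len
        planted.append(spec)
    return gen_sequences(length=length, planted=planted, seed=seed)
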