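"""LUMIER co-immunoprecipitation binding ratios and interaction calls.

LUMIER (LUminescence-based Mammalian IntERactome) probes a bait-prey
interaction with three parallel co-immunoprecipitations: sample A carries
the tagged bait with the tagged prey, sample B replaces the bait with the
empty protein-A/Renilla tag, and sample C replaces the prey with the empty
firefly tag.  Firefly luminescence recovered from the precipitate measures
how much prey came down with the bait; dividing the sample-A firefly
signal by the B and C control signals yields the binding ratios

    R_op = FL(A) / FL(B)      (prey specificity)
    R_ob = FL(A) / FL(C)      (bait specificity)

and both ratios strictly above 1.5 call a reliable interaction.  Renilla
luminescence in the precipitate reports whether the bait itself was
immunoprecipitated (``bait_ip_ok``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LumierTriplet",
    "BindingRatios",
    "binding_ratios",
    "batch_calls",
    "read_lumier_csv",
]

INTERACTION_THRESHOLD = 1.5
LUMIER_COLUMNS = ["bait", "prey", "sample", "replicate", "firefly", "renilla"]


@dataclass
class LumierTriplet:
    """Replicate luminescence readings for co-IP samples A, B and C.

    A: bait + prey; B: tag-only bait + prey; C: bait + tag-only prey.
    """

    bait_id: str
    prey_id: str
    firefly_a: np.ndarray
    firefly_b: np.ndarray
    firefly_c: np.ndarray
    renilla_a: np.ndarray = field(default_factory=lambda: np.array([]))
    renilla_b: np.ndarray = field(default_factory=lambda: np.array([]))
    renilla_c: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        for name in ("firefly_a", "firefly_b", "firefly_c",
                     "renilla_a", "renilla_b", "renilla_c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("firefly_a", "firefly_b", "firefly_c"):
            if len(getattr(self, name)) < 1:
                raise ValueError(f"{name}: at least one replicate required")


@dataclass
class BindingRatios:
    bait_id: str
    prey_id: str
    r_op: float
    r_ob: float
    interaction: bool
    bait_ip_ok: bool


def _aggregate(values: np.ndarray, geometric: bool) -> float:
    if geometric:
        return float(np.exp(np.mean(np.log(values))))
    return float(np.mean(values))


def binding_ratios(
    triplet: LumierTriplet,
    threshold: float = INTERACTION_THRESHOLD,
    floor: float = 1e-9,
    geometric: bool = False,
    bait_ip_factor: float = 2.0,
) -> BindingRatios:
    """Compute R_op, R_ob and the interaction call for one bait-prey pair.

    Replicates are aggregated by arithmetic mean (geometric optional)
    after flooring at ``floor`` to keep background-subtracted readings
    positive.  The interaction call is strict: both ratios must exceed
    ``threshold``.  ``bait_ip_ok`` requires the sample-A Renilla signal to
    exceed ``bait_ip_factor`` times the B-sample Renilla background (true
    when no Renilla readings are provided).
    """
    fa = np.maximum(triplet.firefly_a, floor)
    fb = np.maximum(triplet.firefly_b, floor)
    fc = np.maximum(triplet.firefly_c, floor)
    mb = _aggregate(fb, geometric)
    mc = _aggregate(fc, geometric)
    if mb <= floor and np.all(triplet.firefly_b <= 0):
        raise ValueError(
            f"{triplet.bait_id}/{triplet.prey_id}: sample B firefly signal is all "
            "zero; R_op undefined"
        )
    if mc <= floor and np.all(triplet.firefly_c <= 0):
        raise ValueError(
            f"{triplet.bait_id}/{triplet.prey_id}: sample C firefly signal is all "
            "zero; R_ob undefined"
        )
    r_op = _aggregate(fa, geometric) / mb
    r_ob = _aggregate(fa, geometric) / mc
    bait_ip_ok = True
    if len(triplet.renilla_a) and len(triplet.renilla_b):
        bait_ip_ok = bool(
            np.mean(triplet.renilla_a) > bait_ip_factor * np.mean(triplet.renilla_b)
        )
    return BindingRatios(
        bait_id=triplet.bait_id,
        prey_id=triplet.prey_id,
        r_op=r_op,
        r_ob=r_ob,
        interaction=bool(r_op > threshold and r_ob > threshold),
        bait_ip_ok=bait_ip_ok,
    )


def read_lumier_csv(path) -> list[LumierTriplet]:
    """Read the tidy LUMIER CSV (bait, prey, sample in {A,B,C}, replicate,
    firefly, renilla) into triplets, one per (bait, prey), in file order."""
    df = pd.read_csv(path)
    missing = [c for c in LUMIER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LUMIER table is missing column(s) {missing}")
    return dataframe_to_triplets(df)


def dataframe_to_triplets(df: pd.DataFrame) -> list[LumierTriplet]:
    triplets = []
    for (bait, prey), grp in df.groupby(["bait", "prey"], sort=False):
        kw = {}
        for sample in "ABC":
            rows = grp[grp["sample"] == sample]
            if len(rows) == 0:
                raise ValueError(f"{bait}/{prey}: sample {sample} missing")
            kw[f"firefly_{sample.lower()}"] = rows["firefly"].to_numpy(float)
            kw[f"renilla_{sample.lower()}"] = rows["renilla"].to_numpy(float)
        triplets.append(LumierTriplet(bait_id=bait, prey_id=prey, **kw))
    return triplets


def batch_calls(
    triplets: list[LumierTriplet],
    threshold: float = INTERACTION_THRESHOLD,
    **kwargs,
) -> pd.DataFrame:
    """One BindingRatios row per (bait, prey), in input order."""
    rows = []
    for t in triplets:
        try:
            br = binding_ratios(t, threshold=threshold, **kwargs)
        except ValueError as exc:
            raise ValueError(f"pair {t.bait_id}/{t.prey_id}: {exc}") from exc
        rows.append(
            {
                "bait": br.bait_id,
                "prey": br.prey_id,
                "r_op": br.r_op,
                "r_ob": br.r_ob,
                "interaction": br.interaction,
                "bait_ip_ok": br.bait_ip_ok,
            }
        )
    return pd.DataFrame(
        rows, columns=["bait", "prey", "r_op", "r_ob", "interaction", "bait_ip_ok"]
    )
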