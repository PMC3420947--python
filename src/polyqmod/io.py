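"""File input/output: FASTA, TSV/BED tracks, plate CSVs, CD spectra.

Thin wrappers so every stage reads and writes the plain-text formats the
pipeline exchanges: multi-record (optionally aligned) FASTA via Biopython,
tab-separated profile/classification tracks, BED (0-based half-open) for
tract and segment coordinates, tidy CSVs for plate and LUMIER tables, and
wavelength/ellipticity CSVs with a YAML metadata sidecar for CD spectra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cdspec import MRESpectrum, RawSpectrum
from .coiledcoil import CCPrediction, CCSegment
from .screen import validate_plate_table
from .seqscan import PolyQTract, ProteinRecord, QProfile, SeqClassification

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "q_profiles_to_frame",
    "classifications_to_frame",
    "tracts_to_bed",
    "cc_prediction_to_frame",
    "segments_to_bed",
    "read_plate_csv",
    "read_cd_csv",
    "write_mre_csv",
]


def read_fasta(path: str | Path, aligned: bool = False) -> list[ProteinRecord]:
    records = [
        ProteinRecord(rec.id, str(rec.seq), aligned=aligned)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_alignment(path: str | Path) -> list[ProteinRecord]:
    """Aligned FASTA; validates equal lengths."""
    records = read_fasta(path, aligned=True)
    L = len(records[0].sequence)
    for rec in records:
        if len(rec.sequence) != L:
            raise ValueError(f"{path}: ragged alignment at record {rec.id!r}")
    return records


def q_profiles_to_frame(profiles: list[QProfile]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "id": p.protein_id,
                "window_start": p.positions,
                "q_fraction": p.q_fraction,
                "run_q_fraction": p.run_q_fraction,
            }
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


def classifications_to_frame(classifications: list[SeqClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.protein_id for c in classifications],
            "is_polyq_protein": [c.is_polyq_protein for c in classifications],
            "is_q_rich": [c.is_q_rich for c in classifications],
            "n_tracts": [len(c.tracts) for c in classifications],
            "max_tract_length": [
                max((t.length for t in c.tracts), default=0) for c in classifications
            ],
            "evidence_start": [
                c.evidence_region[0] if c.evidence_region else np.nan
                for c in classifications
            ],
            "evidence_end": [
                c.evidence_region[1] if c.evidence_region else np.nan
                for c in classifications
            ],
        }
    )


def tracts_to_bed(tracts_by_id: dict[str, list[PolyQTract]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, tracts in tracts_by_id.items():
            for t in tracts:
                fh.write(f"{pid}\t{t.start}\t{t.end}\tpolyQ_{t.length}\n")


def cc_prediction_to_frame(pred: CCPrediction) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pred.protein_id,
            "pos": np.arange(len(pred.score)),
            "score": pred.score,
            "probability": pred.probability,
            "frame": pred.frame,
        }
    )


def segments_to_bed(
    segments_by_id: dict[str, list[CCSegment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pid, segments in segments_by_id.items():
            for s in segments:
                fh.write(f"{pid}\t{s.start}\t{s.end}\tCC\t{s.max_probability:.4f}\n")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return validate_plate_table(pd.read_csv(path))


def read_cd_csv(path: str | Path, meta_path: str | Path) -> RawSpectrum:
    """Spectrum CSV (wavelength_nm, ellipticity_mdeg) + YAML metadata
    sidecar (concentration_M, path_length_cm, n_residues)."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "ellipticity_mdeg"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    meta = yaml.safe_load(Path(meta_path).read_text())
    try:
        return RawSpectrum(
            wavelengths=df["wavelength_nm"].to_numpy(float),
            ellipticity=df["ellipticity_mdeg"].to_numpy(float),
            concentration=float(meta["concentration_M"]),
            path_length=float(meta["path_length_cm"]),
            n_residues=int(meta["n_residues"]),
            name=str(meta.get("name", Path(path).stem)),
        )
    except KeyError as exc:
        raise ValueError(f"{meta_path}: missing metadata key {exc}") from None


def write_mre_csv(spectrum: MRESpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "mre": spectrum.mre}
    ).to_csv(path, index=False)
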