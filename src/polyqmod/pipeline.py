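"""End-to-end orchestration: sequences -> Q/CC calls -> screen -> enrichment.

A run takes a config naming the inputs (FASTA of modifier sequences,
screen plate CSV, optional LUMIER and CD inputs) plus the analysis
parameters, executes each stage through the library modules, and writes
per-stage TSV/JSON outputs into the output directory:

* ``q_classification.tsv`` and ``polyq_tracts.bed`` — sequence scans,
* ``cc_segments.bed`` and ``cc_calls.tsv`` — coiled-coil predictions,
* ``modifier_calls.tsv`` — toxicity/aggregation calls per modifier,
* ``cross_table.tsv`` — the 3x3 toxicity-by-aggregation grid,
* ``lumier_calls.csv`` / ``cd_result.json`` — when those inputs are given,
* ``enrichment.json`` — coiled-coil prevalence vs the proteome background,
* ``report.json`` — the combined modifier table and all parameters.

Defaults mirror the screen's published settings: Q window 50, coiled-coil
window 28 at probability 0.8, the 20% three-experiment toxicity rule at
alpha 0.05, LUMIER ratio 1.5, CD ratio 1.0, Swiss-Prot background
73,427 proteins at 20.3% coiled-coil prevalence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cdspec, coiledcoil, enrichment, interaction, io, screen, seqscan

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameters and input paths for one pipeline run."""

    out_dir: str
    fasta: str | None = None
    plate_csv: str | None = None
    lumier_csv: str | None = None
    cd_fusion_csv: str | None = None
    cd_tag_csv: str | None = None
    cd_meta: str | None = None
    cd_domain_n_residues: int | None = None

    q_window: int = 50
    run_min: int = 5
    cc_window: int = 28
    cc_threshold: float = 0.8
    cc_weighted: bool = False
    matrix_file: str | None = None
    effect_threshold: float = 0.20
    alpha: float = 0.05
    n_experiments: int = 3
    lumier_threshold: float = 1.5
    cd_ratio_threshold: float = 1.0
    background_n: int = 73_427
    background_cc_fraction: float = 0.203
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cc_threshold <= 1:
            raise ValueError("cc_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_threshold <= 0:
            raise ValueError("effect_threshold must be positive")
        if self.lumier_threshold <= 0:
            raise ValueError("lumier_threshold must be positive")
        if self.q_window < 1 or self.cc_window < 1:
            raise ValueError("window sizes must be >= 1")
        if not 0 < self.background_cc_fraction < 1:
            raise ValueError("background_cc_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(config)}

    modifier_table: pd.DataFrame | None = None

    if config.fasta:
        records = io.read_fasta(config.fasta)
        classifications = [seqscan.classify_sequence(r) for r in records]
        cls_frame = io.classifications_to_frame(classifications)
        cls_frame.to_csv(out / "q_classification.tsv", sep="\t", index=False)
        io.tracts_to_bed(
            {c.protein_id: c.tracts for c in classifications}, out / "polyq_tracts.bed"
        )

        matrix = (
            coiledcoil.PropensityMatrix.from_tsv(config.matrix_file)
            if config.matrix_file
            else coiledcoil.load_default_matrix()
        )
        cc_rows = []
        segments_by_id = {}
        for rec in records:
            if len(rec.sequence) < config.cc_window:
                cc_rows.append({"id": rec.id, "has_cc": False, "max_probability": 0.0})
                continue
            pred = coiledcoil.cc_scan(
                rec, matrix, window=config.cc_window, weighted=config.cc_weighted
            )
            segs = coiledcoil.cc_segments(pred, threshold=config.cc_threshold)
            segments_by_id[rec.id] = segs
            cc_rows.append(
                {
                    "id": rec.id,
                    "has_cc": len(segs) > 0,
                    "max_probability": pred.max_probability,
                }
            )
        cc_frame = pd.DataFrame(cc_rows)
        cc_frame.to_csv(out / "cc_calls.tsv", sep="\t", index=False)
        io.segments_to_bed(segments_by_id, out / "cc_segments.bed")

        modifier_table = cls_frame.merge(cc_frame, on="id")

    calls = None
    if config.plate_csv:
        table = io.read_plate_csv(config.plate_csv)
        calls = screen.classify_screen(
            table,
            threshold=config.effect_threshold,
            alpha=config.alpha,
            n_experiments=config.n_experiments,
        )
        calls_frame = pd.DataFrame(
            {
                "id": [c.modifier_id for c in calls],
                "toxicity_call": [c.toxicity_call for c in calls],
                "aggregation_call": [c.aggregation_call for c in calls],
                "aggregation_percent": [c.aggregation_percent for c in calls],
                "combined_class": [c.combined_class for c in calls],
            }
        )
        calls_frame.to_csv(out / "modifier_calls.tsv", sep="\t", index=False)
        kept = [c for c in calls if c.toxicity_call != "excluded"]
        cross = screen.cross_tabulate(kept)
        cross.to_csv(out / "cross_table.tsv", sep="\t")
        report["cross_table"] = {
            tox: {agg: int(cross.loc[tox, agg]) for agg in cross.columns}
            for tox in cross.index
        }
        report["n_excluded"] = len(calls) - len(kept)
        if modifier_table is not None:
            modifier_table = modifier_table.merge(calls_frame, on="id", how="outer")

    if modifier_table is not None:
        modifier_table.to_csv(out / "modifier_table.tsv", sep="\t", index=False)
        report["modifier_table"] = modifier_table.to_dict(orient="records")

    if (
        modifier_table is not None
        and "has_cc" in modifier_table
        and calls is not None
    ):
        bg = enrichment.Background(config.background_n, config.background_cc_fraction)
        enrich: dict = {}
        merged = modifier_table.dropna(subset=["toxicity_call"])
        for group, sub in (
            ("all_modifiers", merged),
            ("enhancers", merged[merged["toxicity_call"] == "enhancer"]),
            ("suppressors", merged[merged["toxicity_call"] == "suppressor"]),
        ):
            n = len(sub)
            if n == 0:
                continue
            k = int(sub["has_cc"].sum())
            chi2, p = enrichment.chisq_vs_background(k, n, bg)
            enrich[group] = {"k_cc": k, "n": n, "chi2": chi2, "p": p}
        (out / "enrichment.json").write_text(json.dumps(enrich, indent=2))
        report["enrichment"] = enrich

    if config.lumier_csv:
        triplets = interaction.read_lumier_csv(config.lumier_csv)
        lum = interaction.batch_calls(triplets, threshold=config.lumier_threshold)
        lum.to_csv(out / "lumier_calls.csv", index=False)
        report["lumier"] = lum.to_dict(orient="records")

    if config.cd_fusion_csv:
        if not (config.cd_tag_csv and config.cd_meta and config.cd_domain_n_residues):
            raise ValueError(
                "cd_fusion_csv requires cd_tag_csv, cd_meta and cd_domain_n_residues"
            )
        meta = yaml.safe_load(Path(config.cd_meta).read_text())
        fusion = io.read_cd_csv(config.cd_fusion_csv, config.cd_meta)
        tag_meta = meta.get("tag", meta)
        tag = cdspec.RawSpectrum(
            wavelengths=pd.read_csv(config.cd_tag_csv)["wavelength_nm"].to_numpy(float),
            ellipticity=pd.read_csv(config.cd_tag_csv)["ellipticity_mdeg"].to_numpy(float),
            concentration=float(tag_meta["concentration_M"]),
            path_length=float(tag_meta["path_length_cm"]),
            n_residues=int(tag_meta["n_residues"]),
            name="tag",
        )
        domain = cdspec.subtract_tag(
            cdspec.smooth(fusion), cdspec.smooth(tag), config.cd_domain_n_residues
        )
        io.write_mre_csv(domain, out / "domain_mre.csv")
        result = cdspec.ellipticity_ratio(domain)
        cd_report = dataclasses.asdict(result)
        (out / "cd_result.json").write_text(json.dumps(cd_report, indent=2))
        report["cd"] = cd_report

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
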