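"""End-to-end orchestration: generate or load a study, classify, compute
densities, run the nonparametric battery, and emit report tables.

Outputs (all plain text, TSV/JSON) mirror the study's reporting layout:
a per-segment density table, a stage × class summary, Kruskal–Wallis +
Dunn tables comparing the four classes within each stage and the four
stages within each class (plus totals), and the biometric regression
table.  A JSON manifest records config, seed, input hashes and outputs so
identical (config, seed, inputs) reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import CLASS_LABELS, SpineClass, classify_all
from .density import (
    DensityRecord,
    biometric_regressions,
    records_frame,
    segment_density,
    stage_summary,
)
from .morphology import DendriticSegment, SpineMetrics
from .stats import dunn_posthoc, kruskal_wallis, normality_check
from .synthetic import StudyConfig, StudyDataset, generate_study

__all__ = ["RunManifest", "run_pipeline", "report_tables", "load_config",
           "write_spine_tsv", "read_spine_tsv"]

logger = logging.getLogger("spinemorph")

SPINE_TSV_COLUMNS = [
    "segment_id",
    "stage",
    "animal_id",
    "total_length_um",
    "has_head",
    "head_diameter_um",
    "neck_max_diameter_um",
    "neck_length_um",
]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int | None
    mode: str
    input_hashes: dict[str, str]
    tool_version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from a YAML/flat key-value file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    kwargs = {}
    for key in (
        "stages",
        "segments_per_stage",
        "segment_length_range",
        "animals_per_stage",
        "seed",
        "phi",
        "with_geometry",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    if "segment_length_range" in kwargs:
        kwargs["segment_length_range"] = tuple(kwargs["segment_length_range"])
    return StudyConfig(**kwargs)


def write_spine_tsv(segments: list[DendriticSegment], path: Path,
                    with_classes: bool = False) -> None:
    """Emit the per-spine geometry table (one row per spine)."""
    rows = []
    for seg in segments:
        classes = seg.spine_classes if seg.spine_classes is not None else [None] * len(seg.spines)
        for sp, lab in zip(seg.spines, classes):
            row = {
                "segment_id": seg.segment_id,
                "stage": seg.stage,
                "animal_id": seg.animal_id,
                "total_length_um": round(sp.total_length, 6),
                "has_head": int(sp.has_head),
                "head_diameter_um": round(sp.head_diameter, 6),
                "neck_max_diameter_um": round(sp.neck_max_diameter, 6),
                "neck_length_um": round(sp.neck_length, 6),
            }
            if with_classes:
                row["class"] = "" if lab is None else lab.reported
                row["gap_flag"] = "" if lab is None else int(lab.gap_flag)
            rows.append(row)
    cols = SPINE_TSV_COLUMNS + (["class", "gap_flag"] if with_classes else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_segment_tsv(segments: list[DendriticSegment], path: Path) -> None:
    """Emit the per-segment table (arc lengths; needed to compute densities)."""
    rows = [
        {
            "segment_id": s.segment_id,
            "stage": s.stage,
            "animal_id": s.animal_id,
            "arc_length_um": round(s.arc_length, 6),
            "n_spines": len(s.spines),
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spine_tsv(
    spine_path: str | Path, segment_path: str | Path
) -> list[DendriticSegment]:
    """Rebuild segments from the spine-geometry and segment tables.

    The polyline is not stored in the tables; a straight placeholder
    polyline of the recorded arc length is attached (density and
    statistics only need the arc length).
    """
    import numpy as np

    spines_df = pd.read_csv(spine_path, sep="\t")
    seg_df = pd.read_csv(segment_path, sep="\t")
    by_seg: dict[str, list[SpineMetrics]] = {}
    for _, r in spines_df.iterrows():
        has_head = bool(r["has_head"])
        m = SpineMetrics(
            total_length=float(r["total_length_um"]),
            has_head=has_head,
            head_diameter=float(r["head_diameter_um"]) if has_head else 0.0,
            neck_max_diameter=float(r["neck_max_diameter_um"]) if has_head else 0.0,
            neck_length=float(r["neck_length_um"]) if has_head else 0.0,
        )
        by_seg.setdefault(str(r["segment_id"]), []).append(m)
    segments = []
    for _, r in seg_df.iterrows():
        L = float(r["arc_length_um"])
        points = np.array([[0.0, 0.0, 0.0], [L, 0.0, 0.0]])
        segments.append(
            DendriticSegment(
                points=points,
                radii=np.array([0.5, 0.5]),
                arc_length=L,
                spines=by_seg.get(str(r["segment_id"]), []),
                stage=str(r["stage"]),
                animal_id=str(r["animal_id"]),
                segment_id=str(r["segment_id"]),
                allow_short=True,
            )
        )
    return segments


def _kw_dunn_frame(groups: dict[str, list[float]], adjust: str) -> pd.DataFrame:
    """One K-W test plus all pairwise Dunn rows, as a tidy frame."""
    labels = list(groups)
    samples = [groups[k] for k in labels]
    kw = kruskal_wallis(samples)
    rows = []
    for pr in dunn_posthoc(samples, labels=labels, adjust=adjust):
        rows.append(
            {
                "group_a": pr.group_a,
                "group_b": pr.group_b,
                "KW_H": round(kw.H, 4),
                "KW_df": kw.df,
                "KW_p": kw.p,
                "Z": round(pr.Z, 4),
                "p_raw": pr.p_raw,
                "p_adjusted": pr.p_adjusted,
                "significance": pr.code,
            }
        )
    return pd.DataFrame(rows)


def compute_statistics(
    records: list[DensityRecord], adjust: str = "none"
) -> dict[str, pd.DataFrame]:
    """The full inferential battery on a set of density records."""
    df = records_frame(records)
    stages = list(dict.fromkeys(df["stage"]))

    by_stage = []  # classes compared within each stage
    for s in stages:
        sub = df[df["stage"] == s]
        groups = {c: sub[f"density_{c}"].tolist() for c in CLASS_LABELS}
        frame = _kw_dunn_frame(groups, adjust)
        frame.insert(0, "stage", s)
        by_stage.append(frame)

    by_class = []  # stages compared within each class
    for c in CLASS_LABELS:
        groups = {s: df.loc[df["stage"] == s, f"density_{c}"].tolist() for s in stages}
        frame = _kw_dunn_frame(groups, adjust)
        frame.insert(0, "class", c)
        by_class.append(frame)

    totals = _kw_dunn_frame(
        {s: df.loc[df["stage"] == s, "density_total"].tolist() for s in stages},
        adjust,
    )

    W, p, is_normal = normality_check(df["density_total"].to_numpy())
    logger.info(
        "normality gate (advisory): Shapiro-Wilk W=%.4f p=%.3g normal=%s; "
        "proceeding nonparametrically",
        W, p, is_normal,
    )
    return {
        "kw_dunn_by_stage": pd.concat(by_stage, ignore_index=True),
        "kw_dunn_by_class": pd.concat(by_class, ignore_index=True),
        "kw_dunn_total": totals,
    }


def report_tables(stats_frames: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Render statistics frames as aligned text tables (markdown-ish)."""
    if not stats_frames:
        raise ValueError("no results to report")
    out = {}
    for name, frame in stats_frames.items():
        if frame.empty:
            raise ValueError(f"results table {name!r} is empty")
        out[name] = frame.to_string(index=False) + "\n"
    return out


def run_pipeline(
    config: StudyConfig | str | Path,
    out_dir: str | Path,
    mode: str = "synthetic",
    spine_tsv: str | Path | None = None,
    segment_tsv: str | Path | None = None,
    biometrics_tsv: str | Path | None = None,
    adjust: str = "none",
) -> RunManifest:
    """Run the full analysis and write the six report files plus a manifest.

    ``synthetic`` mode generates the study from the calibrated rate table;
    ``from_files`` mode reads spine/segment/biometrics TSVs and never
    touches the generator.
    """
    if mode not in ("synthetic", "from_files"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(config, (str, Path)):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes: dict[str, str] = {}

    if mode == "synthetic":
        dataset = generate_study(config)
        dataset.classify()
        segments = dataset.segments
        animals = dataset.animals
    else:
        if spine_tsv is None or segment_tsv is None:
            raise FileNotFoundError("from_files mode needs spine and segment TSVs")
        for p in (spine_tsv, segment_tsv, biometrics_tsv):
            if p is not None:
                p = Path(p)
                if not p.exists():
                    raise FileNotFoundError(p)
                input_hashes[p.name] = _sha256(p)
        segments = read_spine_tsv(spine_tsv, segment_tsv)
        for seg in segments:
            seg.spine_classes, _ = classify_all(seg.spines)
        animals = (
            pd.read_csv(biometrics_tsv, sep="\t") if biometrics_tsv is not None else None
        )

    records = [segment_density(s) for s in segments]
    summary = stage_summary(records)
    stats_frames = compute_statistics(records, adjust=adjust)

    outputs = []

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    _emit("density_records.tsv",
          lambda p: records_frame(records).to_csv(p, sep="\t", index=False))
    flat = summary.table.copy()
    flat.columns = [f"{c}_{s}" for c, s in flat.columns]
    _emit("summary_table.tsv",
          lambda p: flat.to_csv(p, sep="\t", index_label="stage"))
    for key in ("kw_dunn_by_stage", "kw_dunn_by_class", "kw_dunn_total"):
        _emit(f"{key}.tsv",
              lambda p, k=key: stats_frames[k].to_csv(p, sep="\t", index=False))

    if animals is not None and len(animals):
        dens = records_frame(records).groupby("animal_id")["density_total"].mean()
        merged = animals.merge(
            dens.rename("mean_density"), left_on="animal_id", right_index=True
        )
        reg = biometric_regressions(merged)
        reg_df = pd.DataFrame([r.__dict__ for r in reg])
    else:
        reg_df = pd.DataFrame(
            columns=["metric", "slope", "intercept", "r_squared", "p_value", "significant"]
        )
    _emit("regressions.tsv", lambda p: reg_df.to_csv(p, sep="\t", index=False))

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        mode=mode,
        input_hashes=input_hashes,
        tool_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return manifest
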