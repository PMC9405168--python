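"""Spine density per 10 µm of dendritic arc length, per segment and per stage.

Densities are normalised by each segment's true arc length rather than a
fixed 10 µm window: the tracing rule requires *at least* 10 µm, so traced
lengths vary.  Class densities partition the total exactly on every record.
Gap-rule stubbies (S_EXT) count toward S and toward totals, with their
tally carried separately for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CLASS_LABELS
from .morphology import DendriticSegment

__all__ = [
    "DensityRecord",
    "SummaryTable",
    "RegressionResult",
    "segment_density",
    "records_frame",
    "stage_summary",
    "biometric_regressions",
]


@dataclass(frozen=True)
class DensityRecord:
    """Per-segment spine counts and densities (spines/10 µm)."""

    segment_id: str
    stage: str
    animal_id: str
    arc_length: float
    counts: dict[str, int]  # keys M, LT, S, F
    count_total: int
    count_s_ext: int
    densities: dict[str, float]
    density_total: float


def segment_density(segment: DendriticSegment) -> DensityRecord:
    """Compute the density record of one classified segment.

    density_c = count_c / arc_length × 10 for each class c; the class
    densities sum exactly to the total.
    """
    if segment.spine_classes is None:
        raise ValueError(f"segment {segment.segment_id} is not classified")
    if not segment.arc_length > 0:
        raise ValueError("arc length must be positive")
    counts = {c: 0 for c in CLASS_LABELS}
    s_ext = 0
    for lab in segment.spine_classes:
        counts[lab.reported] += 1
        s_ext += lab.gap_flag
    total = sum(counts.values())
    scale = 10.0 / segment.arc_length
    densities = {c: counts[c] * scale for c in CLASS_LABELS}
    return DensityRecord(
        segment_id=segment.segment_id,
        stage=segment.stage,
        animal_id=segment.animal_id,
        arc_length=segment.arc_length,
        counts=counts,
        count_total=total,
        count_s_ext=s_ext,
        densities=densities,
        density_total=total * scale,
    )


def records_frame(records: list[DensityRecord]) -> pd.DataFrame:
    """Flatten density records to a DataFrame (one row per segment)."""
    rows = []
    for r in records:
        row = {
            "segment_id": r.segment_id,
            "stage": r.stage,
            "animal_id": r.animal_id,
            "arc_length_um": r.arc_length,
            "count_total": r.count_total,
            "count_s_ext": r.count_s_ext,
            "density_total": r.density_total,
        }
        for c in CLASS_LABELS:
            row[f"count_{c}"] = r.counts[c]
            row[f"density_{c}"] = r.densities[c]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryTable:
    """Mean ± SE spine densities per stage × class, plus pooled class means.

    ``table`` has one row per stage in first-appearance order and a final
    ``pooled`` row aggregating all segments; columns are a (class, stat)
    MultiIndex with stats mean, se, n and classes M, LT, S, F, total.
    SE is the sample standard deviation (ddof=1) over segments divided by √n.
    """

    table: pd.DataFrame

    def mean(self, stage: str, cls: str = "total") -> float:
        return float(self.table.loc[stage, (cls, "mean")])

    def se(self, stage: str, cls: str = "total") -> float:
        return float(self.table.loc[stage, (cls, "se")])


def stage_summary(records: list[DensityRecord]) -> SummaryTable:
    """Aggregate density records to mean ± SE per stage and pooled.

    Every stage must contribute at least 2 segments (SE is undefined for
    n = 1).
    """
    if not records:
        raise ValueError("no density records")
    df = records_frame(records)
    stages = list(dict.fromkeys(df["stage"]))
    counts_per_stage = df["stage"].value_counts()
    thin = counts_per_stage[counts_per_stage < 2]
    if len(thin):
        raise ValueError(
            f"stage(s) with fewer than 2 segments, SE undefined: {list(thin.index)}"
        )
    cols = list(CLASS_LABELS) + ["total"]
    out = {}
    for label, sub in [*((s, df[df["stage"] == s]) for s in stages), ("pooled", df)]:
        row = {}
        for c in cols:
            vals = sub[f"density_{c}" if c != "total" else "density_total"].to_numpy()
            n = len(vals)
            row[(c, "mean")] = float(np.mean(vals))
            row[(c, "se")] = float(np.std(vals, ddof=1) / np.sqrt(n))
            row[(c, "n")] = n
        out[label] = row
    table = pd.DataFrame(out).T
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["class", "stat"])
    return SummaryTable(table=table)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of density on one log10-transformed biometric."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    significant: bool  # R² >= 0.7 AND p < 0.05


def biometric_regressions(
    animals: pd.DataFrame,
    r2_threshold: float = 0.7,
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """Regress per-animal mean spine density on log10 biometrics.

    ``animals`` needs columns TL_cm, TW_g, BW_g (all positive) and
    mean_density, one row per animal, n ≥ 3.  Body measures span orders of
    magnitude across life stages, so each is log10-transformed before the
    ordinary least-squares fit.  A correlation is flagged significant only
    when R² ≥ ``r2_threshold`` and the slope p < ``alpha``.
    """
    required = {"TL_cm", "TW_g", "BW_g", "mean_density"}
    missing = required - set(animals.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(animals) < 3:
        raise ValueError("need at least 3 animals")
    results = []
    y = animals["mean_density"].to_numpy(dtype=float)
    for col in ("TL_cm", "TW_g", "BW_g"):
        x = animals[col].to_numpy(dtype=float)
        if not np.all(x > 0):
            raise ValueError(f"{col} must be strictly positive for log transform")
        if np.ptp(y) == 0:  # constant density: no association by definition
            results.append(
                RegressionResult(col, 0.0, float(y[0]), 0.0, 1.0, False)
            )
            continue
        fit = sps.linregress(np.log10(x), y)
        r2 = float(fit.rvalue**2)
        p = float(fit.pvalue)
        results.append(
            RegressionResult(
                metric=col,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=r2,
                p_value=p,
                significant=bool(r2 >= r2_threshold and p < alpha),
            )
        )
    return results
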