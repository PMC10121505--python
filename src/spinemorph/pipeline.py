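"""End-to-end orchestration of the measurement pipeline.

``run_measure`` executes slice standardization -> segmentation -> mask
cleanup -> vertebra splitting/labeling -> corner detection -> morphometry
-> deformity classification and returns a :class:`CaseReport` whose
provenance (config hash, seeds) suffices to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StandardSlice
from .geometry import clean_mask, detect_corners, lumbar_components, split_and_label
from .morphometry import DEFAULT_NORMS, ReferenceNorms, classify, measure
from .segmentation import CorruptionConfig, segment
from .stats import ContingencyCounts, diagnostic_metrics

__all__ = ["PipelineConfig", "CaseReport", "run_measure", "run_evaluate",
           "StageError"]

LUMBAR = ("L1", "L2", "L3", "L4", "L5")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    backend: str = "oracle"
    corruption: CorruptionConfig | None = None
    corruption_seed: int = 0
    corner_seed: int = 0
    corner_iterations: int = 50
    min_area_mm2: float = 50.0
    max_dist_mm: float = 40.0
    labels: list[str] | None = None
    sacrum_present: bool = False
    norms: ReferenceNorms = field(default_factory=lambda: DEFAULT_NORMS)
    overall_height_mode: str = "mean"

    def digest(self) -> str:
        payload = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in self.__dict__.items()}
        payload["norms"] = self.norms.as_dict()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CaseReport:
    case_id: str
    rows: list[dict]
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        float_cols = df.select_dtypes(float).columns
        df[float_cols] = df[float_cols].round(4)
        df.to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"case_id": self.case_id, "vertebrae": self.rows,
             "provenance": self.provenance}, indent=2, default=float))


def run_measure(
    slice_: StandardSlice,
    config: PipelineConfig | None = None,
    *,
    oracle_labels: np.ndarray | None = None,
    model=None,
    case_id: str = "case",
) -> CaseReport:
    """Run the full per-case measurement pipeline on a standardized slice."""
    config = config or PipelineConfig()

    try:
        mask = segment(slice_, backend=config.backend, labels=oracle_labels,
                       model=model, corruption=config.corruption,
                       seed=config.corruption_seed)
    except ValueError as exc:
        raise StageError("segment", str(exc)) from exc

    try:
        cleaned = clean_mask(mask, min_area_mm2=config.min_area_mm2,
                             max_dist_mm=config.max_dist_mm)
        comps = split_and_label(cleaned, labels=config.labels,
                                sacrum_present=config.sacrum_present)
    except Exception as exc:
        raise StageError("post-process", str(exc)) from exc

    rows = []
    measured = {}
    for comp in comps:
        try:
            quad, _all = detect_corners(comp, seed=config.corner_seed,
                                        iterations=config.corner_iterations)
            m = measure(comp.mask, quad, comp.spacing)
        except Exception as exc:
            raise StageError("corners/measure",
                             f"{comp.label}: {exc}") from exc
        measured[comp.label] = m
        rows.append({"label": comp.label, **m.as_dict(),
                     "strategy": quad.strategy,
                     "overlap": quad.overlap})

    order = [c.label for c in comps]
    lumbar = lumbar_components(comps)
    for row in rows:
        label = row["label"]
        if label not in {c.label for c in lumbar}:
            row.update(deformity=None, fractured=None)
            continue
        i = order.index(label)
        neighbors = [measured[order[j]] for j in (i - 1, i + 1)
                     if 0 <= j < len(order)]
        try:
            call = classify(measured[label], neighbors, config.norms,
                            label=label,
                            overall_height_mode=config.overall_height_mode)
        except Exception as exc:
            raise StageError("classify", f"{label}: {exc}") from exc
        row.update(deformity=call.deformity, fractured=call.fractured)

    provenance = {
        "config_hash": config.digest(),
        "backend": config.backend,
        "corner_seed": config.corner_seed,
        "corruption_seed": config.corruption_seed,
        "n_vertebrae": len(comps),
        "orientation": slice_.orientation,
    }
    return CaseReport(case_id=case_id, rows=rows, provenance=provenance)


def run_evaluate(
    calls: pd.DataFrame,
    strata: list[str] | None = None,
    *,
    predicted_col: str = "predicted",
    reference_col: str = "reference",
) -> pd.DataFrame:
    """Per-stratum contingency counts and diagnostic metrics.

    ``calls`` holds one row per vertebra with binary predicted and
    reference labels plus optional grouping columns.  Returns a tidy table
    mirroring a diagnostic-performance layout (one row per stratum).
    """
    for col in (predicted_col, reference_col):
        if col not in calls.columns:
            raise ValueError(f"calls table is missing column {col!r}")

    groups: list[tuple[str, pd.DataFrame]] = [("all", calls)]
    if strata:
        for col in strata:
            if col not in calls.columns:
                raise ValueError(f"stratum column {col!r} not in calls table")
            for value, sub in calls.groupby(col, sort=True):
                groups.append((f"{col}={value}", sub))

    out_rows = []
    for name, sub in groups:
        if len(sub) == 0:
            continue
        pred = sub[predicted_col].astype(int).to_numpy()
        ref = sub[reference_col].astype(int).to_numpy()
        counts = ContingencyCounts(
            tp=int(((pred == 1) & (ref == 1)).sum()),
            fp=int(((pred == 1) & (ref == 0)).sum()),
            tn=int(((pred == 0) & (ref == 0)).sum()),
            fn=int(((pred == 0) & (ref == 1)).sum()),
            stratum=name,
        )
        metrics = diagnostic_metrics(counts)
        row = {"stratum": name, "n": counts.total, "TP": counts.tp,
               "FP": counts.fp, "TN": counts.tn, "FN": counts.fn}
        for metric, rep in metrics.items():
            row[metric] = round(rep.estimate, 3)
            row[f"{metric}_ci_low"] = round(rep.ci_low, 3)
            row[f"{metric}_ci_high"] = round(rep.ci_high, 3)
        out_rows.append(row)
    return pd.DataFrame(out_rows)
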