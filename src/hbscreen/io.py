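"""Readers and writers for the pipeline's plain-text formats.

One fixed CSV dialect throughout: UTF-8, header row, dot decimal separator, no
thousands separators.  The peak-area table is long-format with columns
``sample_id,peptide_id,area,is_area,noise,age_days,genotype`` (noise and
genotype may be empty).  Calls and ROC reports are TSV; summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quantify import InputError, PeakMeasurement, SampleRecord
from .risk_models import ROCCurve
from .screening import ScreeningCall

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "samples_to_frame",
    "frame_to_samples",
    "write_peak_table",
    "read_peak_table",
    "write_truth",
    "read_truth",
    "calls_to_frame",
    "write_calls",
    "read_calls",
    "write_roc_report",
    "write_json",
]

PEAK_TABLE_COLUMNS = ["sample_id", "peptide_id", "area", "is_area", "noise",
                      "age_days", "genotype"]


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for m in s.measurements:
            rows.append({
                "sample_id": s.sample_id,
                "peptide_id": m.peptide_id,
                "area": m.area,
                "is_area": m.is_area,
                "noise": m.noise,
                "age_days": s.age_days,
                "genotype": s.truth_genotype,
            })
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def frame_to_samples(df: pd.DataFrame) -> list[SampleRecord]:
    required = {"sample_id", "peptide_id", "area", "is_area"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"peak table lacks columns: {sorted(missing)}")
    samples: list[SampleRecord] = []
    for sid, group in df.groupby("sample_id", sort=True):
        measurements = []
        for _, row in group.iterrows():
            noise = row.get("noise")
            noise = None if noise is None or (isinstance(noise, float) and np.isnan(noise)) else float(noise)
            measurements.append(
                PeakMeasurement(str(sid), str(row["peptide_id"]),
                                float(row["area"]), float(row["is_area"]), noise)
            )
        age = group["age_days"].iloc[0] if "age_days" in group else 0
        geno = group["genotype"].iloc[0] if "genotype" in group else None
        if isinstance(geno, float) and np.isnan(geno):
            geno = None
        samples.append(
            SampleRecord(str(sid), int(age) if not pd.isna(age) else 0,
                         measurements, None if geno is None else str(geno))
        )
    return samples


def write_peak_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    # %.17g preserves float64 exactly across a write/read cycle
    samples_to_frame(samples).to_csv(path, index=False, encoding="utf-8",
                                     float_format="%.17g")


def read_peak_table(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    return frame_to_samples(df)


def write_truth(samples: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sample_id": s.sample_id, "genotype": s.truth_genotype} for s in samples]
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", encoding="utf-8", dtype=str)
    if not {"sample_id", "genotype"} <= set(df.columns):
        raise InputError("truth table needs sample_id and genotype columns")
    return dict(zip(df["sample_id"], df["genotype"]))


def calls_to_frame(calls: Sequence[ScreeningCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_id": c.sample_id,
            "p_alpha": c.p_alpha,
            "p_beta": c.p_beta,
            "category": c.category,
            "severity_band": c.severity_band or "",
            "variants": ";".join(c.variants_detected),
            "reasons": " | ".join(c.reasons),
        }
        for c in calls
    ])


def write_calls(calls: Sequence[ScreeningCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     keep_default_na=False, na_values=[""])
    if "category" not in df.columns:
        raise InputError("calls table needs a category column")
    return df


def write_roc_report(curve: ROCCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "threshold": curve.thresholds,
        "sensitivity": curve.sensitivity,
        "specificity": curve.specificity,
        "J": curve.sensitivity + curve.specificity - 1.0,
    })
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
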