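"""CSV / JSON interchange.

On-disk layout:

* one CSV per trial: a ``sample`` index column plus the 14 signal columns
  (forces in N, knee flexion in degrees);
* a cohort manifest CSV: ``subject_id, group, leg, mass_kg, trial_files``
  (trial paths separated by ``;``, relative to the manifest);
* the processed cohort as a wide CSV, one row per subject-leg, columns
  ``signal@percent`` (e.g. ``RF@37``), plus a JSON metadata sidecar;
* characteristic points as ``signal, percent, p_value`` CSV;
* feature tables as CSV with the group label in the last column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .charpoints import CharacteristicPoint
from .errors import SchemaError
from .preprocess import GaitTrial, ProcessedWaveforms, SubjectRecord
from .signals import N_POINTS, SIGNALS


def write_trial_csv(trial: GaitTrial, path: str | Path) -> None:
    df = pd.DataFrame({"sample": np.arange(trial.n_samples)})
    for name in SIGNALS:
        df[name] = trial.samples[name]
    df.to_csv(path, index=False)


def read_trial_csv(path: str | Path, trial_id: str | None = None) -> GaitTrial:
    df = pd.read_csv(path)
    missing = [s for s in SIGNALS if s not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing signal columns {missing}")
    samples = {s: df[s].to_numpy(dtype=float) for s in SIGNALS}
    return GaitTrial(trial_id=trial_id or Path(path).stem, samples=samples)


def write_cohort(records: list[SubjectRecord], directory: str | Path) -> Path:
    """Write per-trial CSVs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        files = []
        for trial in rec.trials:
            fname = f"{trial.trial_id}.csv"
            write_trial_csv(trial, directory / fname)
            files.append(fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "leg": rec.leg,
                "mass_kg": rec.mass_kg,
                "trial_files": ";".join(files),
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "leg", "mass_kg", "trial_files"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{manifest_path}: manifest needs columns {sorted(required)}"
        )
    records = []
    for row in df.itertuples(index=False):
        trials = [
            read_trial_csv(base / f) for f in str(row.trial_files).split(";") if f
        ]
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                leg=str(row.leg),
                mass_kg=float(row.mass_kg),
                trials=trials,
            )
        )
    return records


def processed_to_frame(cohort: list[ProcessedWaveforms]) -> pd.DataFrame:
    """Wide frame: one row per subject-leg, columns ``signal@percent``."""
    columns = [f"{s}@{p}" for s in SIGNALS for p in range(N_POINTS)]
    data = np.stack([pw.values.ravel() for pw in cohort])
    df = pd.DataFrame(
        data,
        index=pd.Index([pw.subject_id for pw in cohort], name="subject_id"),
        columns=columns,
    )
    df.insert(0, "leg", [pw.leg for pw in cohort])
    df.insert(0, "group", [pw.group for pw in cohort])
    return df


def frame_to_processed(df: pd.DataFrame) -> list[ProcessedWaveforms]:
    value_cols = [f"{s}@{p}" for s in SIGNALS for p in range(N_POINTS)]
    missing = [c for c in value_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"wide cohort frame missing {len(missing)} columns")
    out = []
    for subject_id, row in df.iterrows():
        values = row[value_cols].to_numpy(dtype=float).reshape(len(SIGNALS), N_POINTS)
        out.append(
            ProcessedWaveforms(
                subject_id=str(subject_id),
                group=str(row["group"]),
                leg=str(row["leg"]),
                values=values,
            )
        )
    return out


def write_processed_cohort(
    cohort: list[ProcessedWaveforms], path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    processed_to_frame(cohort).to_csv(path)
    if metadata is not None:
        path.with_suffix(".meta.json").write_text(json.dumps(metadata, indent=2))


def read_processed_cohort(path: str | Path) -> list[ProcessedWaveforms]:
    return frame_to_processed(pd.read_csv(path, index_col="subject_id"))


def points_to_frame(points: list[CharacteristicPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"signal": p.signal, "percent": p.percent, "p_value": p.p_value} for p in points],
        columns=["signal", "percent", "p_value"],
    )


def read_points_csv(path: str | Path) -> list[CharacteristicPoint]:
    df = pd.read_csv(path)
    return [
        CharacteristicPoint(
            signal=str(r.signal), percent=int(r.percent), p_value=float(r.p_value)
        )
        for r in df.itertuples(index=False)
    ]
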