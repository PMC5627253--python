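"""File formats, run configuration and atomic writes.

Everything the pipeline persists is plain text: signals and tables as
CSV, model bundles and evaluation summaries as JSON, configuration as
YAML. A minimal header+samples record format stands in for binary
waveform containers so records stay reviewable and diff-able.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ANNOTATION_COLUMNS, BeatAnnotations, EcgSignal

COHORT_REQUIRED = [
    "patient_id",
    "age",
    "female",
    "smoker",
    "hypertension",
    "diabetes",
    "prior_mi",
    "prior_angiography",
    "event",
    "time_days",
]
COHORT_OPTIONAL = ["trs", "lvef_pct", "bnp"]
HISTORY_COLUMNS = COHORT_REQUIRED[1:8]


class SchemaError(ValueError):
    """A file exists but does not match the documented schema."""


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults reproduce the reference protocol."""

    ecg_dir: str = "."
    cohort_csv: str = "cohort.csv"
    output_dir: str = "out"
    segment_len_s: float = 300.0
    sqi_threshold: float = 0.8
    window_beats: int = 50
    retained_coefficients: int = 2
    hidden_units: int = 13
    n_rounds: int = 1000
    test_fraction: float = 0.2
    horizons: tuple = (365, 60, 30, 14)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.horizons, list):
            cfg.horizons = tuple(cfg.horizons)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        atomic_write_text(path, yaml.safe_dump(d, sort_keys=False))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via temp file + rename so interrupted runs never leave partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_frame(path: str | Path, frame: pd.DataFrame) -> None:
    atomic_write_text(path, frame.to_csv(index=False))


def write_ecg_csv(path: str | Path, sig: EcgSignal) -> None:
    """Plain CSV signal: header comment carries fs/patient/lead metadata."""
    lines = [f"# fs={sig.fs} patient_id={sig.patient_id} lead={sig.lead}"]
    lines.append("sample_index,voltage_mV")
    lines.extend(f"{i},{v:.9g}" for i, v in enumerate(sig.samples))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_ecg(path: str | Path, fs: float | None = None) -> EcgSignal:
    """Read a signal CSV (or header+samples record pair) into an EcgSignal.

    The sampling rate must come from the file metadata or the `fs`
    argument — it is never guessed.
    """
    path = Path(path)
    if path.suffix == ".hea":
        return _read_record(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.lower().startswith("sample_index"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 'sample_index,voltage_mV'")
            try:
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric voltage {parts[1]!r}") from exc
    if fs is None:
        if "fs" not in meta:
            raise SchemaError(f"{path}: sampling rate not present and not provided")
        fs = float(meta["fs"])
    return EcgSignal(
        np.asarray(samples),
        fs,
        patient_id=meta.get("patient_id", path.stem),
        lead=meta.get("lead", "II"),
    )


def write_record(basepath: str | Path, sig: EcgSignal, ann: BeatAnnotations | None = None) -> None:
    """Header + samples record (+ optional fiducial annotation table)."""
    base = Path(basepath)
    atomic_write_text(
        base.with_suffix(".hea"),
        f"{base.stem} {len(sig.samples)} {sig.fs} {sig.patient_id} {sig.lead}\n",
    )
    atomic_write_text(
        base.with_suffix(".dat.csv"),
        "voltage_mV\n" + "\n".join(f"{v:.9g}" for v in sig.samples) + "\n",
    )
    if ann is not None:
        atomic_write_frame(base.with_suffix(".ann.csv"), ann.frame)


def _read_record(hea_path: Path) -> EcgSignal:
    fields = hea_path.read_text().split()
    if len(fields) < 3:
        raise SchemaError(f"{hea_path}: malformed header")
    name, n_samples, fs = fields[0], int(fields[1]), float(fields[2])
    patient_id = fields[3] if len(fields) > 3 else name
    lead = fields[4] if len(fields) > 4 else "II"
    dat = hea_path.with_suffix(".dat.csv")
    samples = pd.read_csv(dat)["voltage_mV"].to_numpy(dtype=float)
    if len(samples) != n_samples:
        raise SchemaError(f"{dat}: {len(samples)} samples, header says {n_samples}")
    return EcgSignal(samples, fs, patient_id=patient_id, lead=lead)


def read_annotations(path: str | Path) -> BeatAnnotations:
    frame = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing annotation columns {sorted(missing)}")
    return BeatAnnotations(frame[ANNOTATION_COLUMNS])


@dataclass
class ExclusionReport:
    included: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # patient_id -> reason

    def summary(self) -> str:
        lines = [f"included: {len(self.included)}", f"excluded: {len(self.excluded)}"]
        lines.extend(f"  {pid}: {reason}" for pid, reason in self.excluded.items())
        return "\n".join(lines)


def read_cohort(
    path: str | Path, usable_beats: dict[str, int] | None = None, min_beats: int = 50
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Load the cohort table, excluding rows that fail the inclusion rules.

    A patient is excluded when any of the seven history features is
    missing, or (when per-patient usable-beat counts are supplied) fewer
    than `min_beats` clean beats are available.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort file") from exc
    missing_cols = set(COHORT_REQUIRED) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing_cols)}")
    report = ExclusionReport()
    keep_rows = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if row[HISTORY_COLUMNS].isna().any():
            bad = [c for c in HISTORY_COLUMNS if pd.isna(row[c])]
            report.excluded[pid] = f"missing_feature:{','.join(bad)}"
            continue
        if usable_beats is not None and usable_beats.get(pid, 0) < min_beats:
            report.excluded[pid] = f"insufficient_beats:{usable_beats.get(pid, 0)}"
            continue
        report.included.append(pid)
        keep_rows.append(row)
    kept = pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else df.iloc[0:0]
    return kept, report


def write_json(path: str | Path, payload: dict) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
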