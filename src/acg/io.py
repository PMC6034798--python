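"""On-disk formats: record containers, cohort manifests, CSV interchange.

One exam record is a directory holding ``meta.json`` (pulse spec, ground
truth medium when synthetic, subject id, record index, quality) and
``samples.f32le`` — the raw waveform as little-endian 32-bit floats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort, cohort_feature_table, covariate_table
from .signal_model import MediumModel, PulseSpec, RecordedSignal

__all__ = [
    "write_record",
    "read_record",
    "record_to_csv",
    "write_cohort",
    "read_meta",
]

SAMPLES_FILE = "samples.f32le"
META_FILE = "meta.json"


def _spec_meta(spec: PulseSpec) -> dict:
    return {
        "frequencies_hz": list(spec.frequencies_hz),
        "amplitudes": list(spec.amplitudes),
        "sampling_rate_hz": spec.sampling_rate_hz,
        "record_duration_s": spec.record_duration_s,
    }


def _medium_meta(medium: MediumModel) -> dict:
    return dataclasses.asdict(medium)


def write_record(
    directory,
    record: RecordedSignal,
    spec: PulseSpec,
    subject_id: Optional[str] = None,
    record_index: Optional[int] = None,
    medium: Optional[MediumModel] = None,
) -> Path:
    """Write one exam record container (meta.json + samples.f32le)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate_hz": record.sampling_rate_hz,
        "duration_s": record.duration_s,
        "quality": record.quality,
        "subject_id": subject_id,
        "record_index": record_index,
        "pulse_spec": _spec_meta(spec),
    }
    if medium is not None:
        meta["medium"] = _medium_meta(medium)
    (directory / META_FILE).write_text(json.dumps(meta, indent=1))
    record.samples.astype("<f4").tofile(directory / SAMPLES_FILE)
    return directory


def read_meta(directory) -> dict:
    return json.loads((Path(directory) / META_FILE).read_text())


def read_record(directory) -> Tuple[RecordedSignal, dict]:
    """Load a record container back into memory."""
    directory = Path(directory)
    meta = read_meta(directory)
    samples = np.fromfile(directory / SAMPLES_FILE, dtype="<f4").astype(np.float64)
    record = RecordedSignal(
        samples=samples,
        sampling_rate_hz=meta["sampling_rate_hz"],
        duration_s=meta["duration_s"],
        quality=meta.get("quality"),
    )
    return record, meta


def spec_from_meta(meta: dict) -> PulseSpec:
    m = meta["pulse_spec"]
    return PulseSpec(
        frequencies_hz=tuple(m["frequencies_hz"]),
        amplitudes=tuple(m["amplitudes"]),
        sampling_rate_hz=m["sampling_rate_hz"],
        record_duration_s=m["record_duration_s"],
    )


def record_to_csv(record: RecordedSignal, path) -> Path:
    """Two-column interchange export: time_s, amplitude."""
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time_axis(), "amplitude": record.samples})
    df.to_csv(path, index=False)
    return path


def write_cohort(directory, cohort: Cohort, features: bool = True) -> Path:
    """Persist a cohort: manifest, covariates CSV, per-exam record containers.

    With ``features=True`` the extracted per-exam feature table is written
    as ``features.csv`` alongside the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {
        k: v for k, v in dataclasses.asdict(cohort.config).items()
        if not isinstance(v, dict)
    }, "subjects": []}
    for subj in cohort.subjects:
        sdir = directory / subj.subject_id
        for i, rec in enumerate(subj.records, start=1):
            write_record(
                sdir / f"record{i}",
                rec,
                subj.pulse_spec,
                subject_id=subj.subject_id,
                record_index=i,
                medium=subj.medium,
            )
        manifest["subjects"].append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "age_years": subj.age_years,
                "head_circumference_cm": subj.head_circumference_cm,
                "path_length_m": subj.path_length_m,
                "covariates": subj.covariates,
                "medium": _medium_meta(subj.medium),
                "latent_toa_us": list(subj.latent_toa_us),
                "latent_att": list(subj.latent_att),
                "n_records": len(subj.records),
                "quality_retries": subj.quality_retries,
            }
        )
    (directory / "cohort.json").write_text(json.dumps(manifest, indent=1))
    covariate_table(cohort).to_csv(directory / "covariates.csv", index=False)
    if features:
        cohort_feature_table(cohort).to_csv(directory / "features.csv", index=False)
    return directory
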