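"""Interchange formats: channel-CSV, paradigm JSON, metadata CSV, SNIRF.

The canonical interchange format is a long-format CSV per subject with
columns ``time_s, channel_id, wavelength_nm, intensity``.  An optional
SNIRF-style HDF5 export (h5py) mirrors the same content for tools that
speak the standard container; both round-trip bit-compatibly through the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, build_montage
from .paradigm import ParadigmTimeline, StimulusEvent
from .preprocess import OpticalRecording, PreprocessError
from .simulate import Cohort

__all__ = [
    "write_recording",
    "read_recording",
    "write_paradigm",
    "read_paradigm",
    "write_snirf",
    "read_snirf",
    "write_cohort",
]


def write_recording(rec: OpticalRecording, path: str | Path) -> Path:
    """Write a recording as long-format CSV."""
    path = Path(path)
    t = rec.times
    frames = []
    for i, ch in enumerate(rec.channel_ids):
        for w, wl in enumerate(rec.wavelengths):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "channel_id": ch,
                        "wavelength_nm": wl,
                        "intensity": rec.intensity[i, w],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_recording(
    path: str | Path,
    sampling_rate: float = 3.91,
    subject_id: str = "",
    montage: Montage | None = None,
) -> OpticalRecording:
    """Read a long-format channel CSV back into an :class:`OpticalRecording`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "channel_id", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise PreprocessError(f"{path.name}: missing column(s) {sorted(missing)}")
    channels = sorted(df["channel_id"].unique())
    wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
    lengths = df.groupby(["channel_id", "wavelength_nm"]).size()
    if lengths.nunique() != 1:
        raise PreprocessError(f"{path.name}: unequal series lengths across channels")
    for ch in channels:
        got = set(df.loc[df.channel_id == ch, "wavelength_nm"].unique())
        if got != set(wavelengths):
            raise PreprocessError(
                f"{path.name}: channel {ch} lacks wavelength(s) "
                f"{sorted(set(wavelengths) - got)}"
            )
    if len(wavelengths) != 2:
        raise PreprocessError(
            f"{path.name}: expected 2 wavelengths, found {wavelengths}"
        )
    n = int(lengths.iloc[0])
    intensity = np.empty((len(channels), 2, n))
    df = df.sort_values(["channel_id", "wavelength_nm", "time_s"])
    for i, ch in enumerate(channels):
        sub = df[df.channel_id == ch]
        for w, wl in enumerate(wavelengths):
            intensity[i, w] = sub.loc[sub.wavelength_nm == wl, "intensity"].to_numpy()
    return OpticalRecording(
        intensity=intensity,
        channel_ids=tuple(int(c) for c in channels),
        sampling_rate=sampling_rate,
        wavelengths=wavelengths,
        subject_id=subject_id or path.stem,
        montage=montage,
    )


def write_paradigm(paradigm: ParadigmTimeline, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "rest_duration": paradigm.rest_duration,
        "baseline_window": paradigm.baseline_window,
        "inter_stimulus_rest": paradigm.inter_stimulus_rest,
        "post_window": paradigm.post_window,
        "events": [asdict(e) for e in paradigm.events],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_paradigm(path: str | Path) -> ParadigmTimeline:
    payload = json.loads(Path(path).read_text())
    events = tuple(StimulusEvent(**e) for e in payload.pop("events"))
    return ParadigmTimeline(events=events, **payload)


def write_snirf(rec: OpticalRecording, path: str | Path) -> Path:
    """Minimal SNIRF-style HDF5 export of a raw recording.

    Layout follows the SNIRF container conventions: one data block with a
    (samples x measurements) matrix and per-measurement source/detector/
    wavelength indices.
    """
    path = Path(path)
    mont = rec.montage if rec.montage is not None else build_montage()
    src_det = {c[0]: (c[1], c[2]) for c in mont.channels}
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        data = nirs.create_group("data1")
        n_meas = len(rec.channel_ids) * 2
        ts = np.empty((rec.n_samples, n_meas))
        m = 0
        for i, ch in enumerate(rec.channel_ids):
            for w in range(2):
                ts[:, m] = rec.intensity[i, w]
                ml = data.create_group(f"measurementList{m + 1}")
                ml.create_dataset("sourceIndex", data=src_det[ch][0])
                ml.create_dataset("detectorIndex", data=src_det[ch][1])
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                ml.create_dataset("channelId", data=int(ch))  # package extension
                m += 1
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=rec.times)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
    return path


def read_snirf(path: str | Path, montage: Montage | None = None) -> OpticalRecording:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]))
        sid = f["nirs/metaDataTags/SubjectID"][()]
        if isinstance(sid, bytes):
            sid = sid.decode()
        n_meas = ts.shape[1]
        chan_of = {}
        for m in range(n_meas):
            ml = data[f"measurementList{m + 1}"]
            ch = int(ml["channelId"][()])
            w = int(ml["wavelengthIndex"][()]) - 1
            chan_of[(ch, w)] = m
    channels = sorted({c for c, _ in chan_of})
    intensity = np.empty((len(channels), 2, ts.shape[0]))
    for i, ch in enumerate(channels):
        for w in range(2):
            intensity[i, w] = ts[:, chan_of[(ch, w)]]
    if len(time) > 1:
        # the time vector is arange(n)/fs; rounding removes float noise so
        # downstream filter coefficients match the original recording's
        fs = round(1.0 / float(np.median(np.diff(time))), 6)
    else:
        fs = 3.91
    return OpticalRecording(
        intensity=intensity,
        channel_ids=tuple(channels),
        sampling_rate=fs,
        wavelengths=wavelengths,
        subject_id=str(sid),
        montage=montage,
    )


def write_cohort(
    cohort: Cohort, out_dir: str | Path, snirf: bool = False
) -> Path:
    """Serialize a synthetic cohort: per-subject CSV (+ optional SNIRF),
    per-subject paradigm JSON, and the metadata table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_recording(s.recording, out / f"{s.subject_id}_raw.csv")
        write_paradigm(s.paradigm, out / f"{s.subject_id}_paradigm.json")
        if snirf:
            write_snirf(s.recording, out / f"{s.subject_id}.snirf")
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    cohort.truth_table().to_csv(out / "generator_truth.csv", index=False)
    return out
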