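"""CSV (and read-only EDF) interchange for recordings and derived artefacts.

CSV is the canonical format: one row per IP sample with columns
``time_s, ip, hr, spo2``; the slow numeric channels appear only on the
rows nearest their own sample times and are empty elsewhere.  On read,
missing numeric values are forward-filled for up to 5 s and left NaN
beyond that.  EDF is supported read-only through mne.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import IBISeries, PhysioRecording
from .simulate import GroundTruth

_FLOAT_FMT = "%.6f"


def write_recording_csv(recording: PhysioRecording, path) -> None:
    n = recording.ip.size
    df = pd.DataFrame(
        {
            "time_s": recording.ip_times,
            "ip": recording.ip,
            "hr": np.full(n, np.nan),
            "spo2": np.full(n, np.nan),
        }
    )
    tn = recording.numeric_times - recording.start_time
    rows = np.clip(np.round(tn * recording.ip_rate).astype(int), 0, n - 1)
    df.loc[rows, "hr"] = recording.hr
    df.loc[rows, "spo2"] = recording.spo2
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording_csv(
    path,
    subject_id: str | None = None,
    numeric_rate: float | None = None,
    ffill_limit_s: float = 5.0,
) -> PhysioRecording:
    df = pd.read_csv(path)
    for col in ("time_s", "ip"):
        if col not in df.columns:
            raise ValueError(f"recording CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("recording CSV must contain at least two samples")
    ip_rate = 1.0 / float(np.median(np.diff(t)))
    start_time = float(t[0])

    def numeric_channel(col: str) -> tuple[np.ndarray, float]:
        if col not in df.columns:
            return np.empty(0), 1.0
        vals = df[col].to_numpy(dtype=float)
        present = np.isfinite(vals)
        if not present.any():
            return np.empty(0), 1.0
        tp = t[present] - start_time
        rate = numeric_rate
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(tp))) if tp.size > 1 else 1.0
        n_num = int(round((t[-1] - start_time + 1.0 / ip_rate) * rate))
        grid = np.full(max(n_num, 1), np.nan)
        idx = np.clip(np.round(tp * rate).astype(int), 0, grid.size - 1)
        grid[idx] = vals[present]
        ser = pd.Series(grid).ffill(limit=max(1, int(round(ffill_limit_s * rate))))
        return ser.to_numpy(), rate

    hr, nrate = numeric_channel("hr")
    spo2, _ = numeric_channel("spo2")
    return PhysioRecording(
        subject_id=subject_id or Path(path).stem,
        ip=df["ip"].to_numpy(dtype=float),
        ip_rate=ip_rate,
        hr=hr,
        spo2=spo2,
        numeric_rate=nrate,
        start_time=start_time,
    )


def recording_from_raw(
    raw,
    ip_channel: str,
    hr_channel: str | None = None,
    spo2_channel: str | None = None,
    numeric_rate: float = 1.0,
    subject_id: str = "edf",
) -> PhysioRecording:
    """Build a recording from an mne Raw object (EDF channel mapping)."""
    sfreq = float(raw.info["sfreq"])
    ip = raw.get_data(picks=[ip_channel])[0]

    def numeric(ch: str | None) -> np.ndarray:
        if ch is None or ch not in raw.ch_names:
            return np.full(int(round(ip.size / sfreq * numeric_rate)), np.nan)
        data = raw.get_data(picks=[ch])[0]
        step = max(1, int(round(sfreq / numeric_rate)))
        return data[::step]

    return PhysioRecording(
        subject_id=subject_id,
        ip=ip,
        ip_rate=sfreq,
        hr=numeric(hr_channel),
        spo2=numeric(spo2_channel),
        numeric_rate=numeric_rate,
    )


def read_recording_edf(
    path,
    ip_channel: str = "Resp",
    hr_channel: str | None = "HR",
    spo2_channel: str | None = "SpO2",
    numeric_rate: float = 1.0,
    subject_id: str | None = None,
) -> PhysioRecording:
    """Read an EDF export via mne (requires the optional ``edf`` extra)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires mne; install ibikit[edf]") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return recording_from_raw(
        raw,
        ip_channel,
        hr_channel,
        spo2_channel,
        numeric_rate,
        subject_id or Path(path).stem,
    )


# --- derived artefacts ------------------------------------------------------


def write_truth(truth: GroundTruth, outdir) -> None:
    """Ground-truth annotations, one CSV per annotation kind."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"breath_time_s": truth.breath_times}).to_csv(
        outdir / "breaths.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        [{"start_s": p.start, "end_s": p.end, "kind": p.kind} for p in truth.pause_intervals]
    ).to_csv(outdir / "pauses.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [{"start_s": a, "end_s": b} for a, b in truth.artefact_intervals]
    ).to_csv(outdir / "artefacts.csv", index=False, float_format=_FLOAT_FMT)
    events = [
        {"channel": "hr", "start_s": s, "nadir": v} for s, v in truth.hr_events
    ] + [{"channel": "spo2", "start_s": s, "nadir": v} for s, v in truth.spo2_events]
    pd.DataFrame(events, columns=["channel", "start_s", "nadir"]).to_csv(
        outdir / "events.csv", index=False, float_format=_FLOAT_FMT
    )


def write_breaths_csv(breath_times: np.ndarray, path) -> None:
    pd.DataFrame({"breath_time_s": np.asarray(breath_times, dtype=float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_ibis_csv(ibis: IBISeries, path) -> None:
    pd.DataFrame(
        {
            "ibi_start_s": ibis.start,
            "ibi_end_s": ibis.end,
            "duration_s": ibis.duration,
            "valid": ibis.valid,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ibis_csv(path) -> IBISeries:
    df = pd.read_csv(path)
    return IBISeries(
        start=df["ibi_start_s"].to_numpy(dtype=float),
        end=df["ibi_end_s"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
    )


def write_pauses_csv(pauses, path) -> None:
    pd.DataFrame(
        [{"start_s": a, "end_s": b, "duration_s": d} for a, b, d in pauses]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_pauses_bed(pauses, subject_id: str, path) -> None:
    """BED-like 3-column text (subject, start_s, end_s), tab-separated."""
    with open(path, "w") as fh:
        for a, b, _d in pauses:
            fh.write(f"{subject_id}\t{a:.6f}\t{b:.6f}\n")


def write_features_csv(candidates, features, labels, path) -> None:
    rows = []
    for k, (cand, feats) in enumerate(zip(candidates, features)):
        row = {
            "subject_id": cand.subject_id,
            "start_s": cand.start,
            "end_s": cand.end,
            "duration_s": cand.duration,
            "rms_during": feats.rms_during,
            "rms_pre10": feats.rms_pre10,
            "rms_post10": feats.rms_post10,
            "delta_hr60": feats.delta_hr60,
            "delta_spo2_60": feats.delta_spo2_60,
        }
        if labels is not None:
            row["label"] = labels[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
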