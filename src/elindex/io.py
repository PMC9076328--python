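"""Readers and writers: CSV recordings/annotations, EDF input, result tables.

CSV is the canonical interchange (headered, UTF-8, '.' decimal): recordings
as ``time_s,c3_uV,c4_uV`` with an annotation sidecar
``event,onset_s,duration_s``.  EDF/EDF+ input is supported through mne
(imported lazily); channel labels are matched case-insensitively against
configurable aliases for the C3-A2 / C4-A1 derivations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Annotation, Recording

DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "C3": ("c3-a2", "c3a2", "c3-m2", "c3"),
    "C4": ("c4-a1", "c4a1", "c4-m1", "c4"),
}


def read_annotations_csv(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    required = {"event", "onset_s", "duration_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"invalid annotations: need columns {sorted(required)}")
    return [
        Annotation(str(r.event), float(r.onset_s), float(r.duration_s))
        for r in df.itertuples()
    ]


def write_annotations_csv(annotations: list[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"event": a.event, "onset_s": a.onset_s, "duration_s": a.duration_s}
         for a in annotations]
    ).to_csv(path, index=False)


def _read_recording_csv(path: Path, subject_id: str) -> tuple[np.ndarray, np.ndarray, float]:
    df = pd.read_csv(path)
    for col in ("time_s", "c3_uV", "c4_uV"):
        if col not in df.columns:
            raise ValueError(f"channel not found: column {col!r} missing in {path.name}")
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) < 1 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("inconsistent rates: irregular time axis")
    fs = 1.0 / float(np.median(dt))
    return df["c3_uV"].to_numpy(float), df["c4_uV"].to_numpy(float), fs


def _read_recording_edf(
    path: Path, aliases: dict[str, tuple[str, ...]]
) -> tuple[np.ndarray, np.ndarray, float, list[Annotation]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    lower = {name.lower().strip(): name for name in raw.ch_names}
    picks = {}
    for target, names in aliases.items():
        found = next((lower[a] for a in names if a in lower), None)
        if found is None:
            raise ValueError(f"channel not found: no alias of {target} in {raw.ch_names}")
        picks[target] = found
    fs = float(raw.info["sfreq"])
    data = {t: raw.get_data(picks=[n])[0] * 1e6 for t, n in picks.items()}  # V -> uV
    anns = [
        Annotation(str(d), float(o), float(du))
        for d, o, du in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
    ]
    return data["C3"], data["C4"], fs, anns


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    annotations: str | Path | None = None,
    subject_id: str | None = None,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> Recording:
    """Read a two-channel recording from CSV or EDF, merging sidecar events."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    subject = subject_id if subject_id is not None else path.stem
    anns: list[Annotation] = []
    if fmt == "csv":
        c3, c4, fs = _read_recording_csv(path, subject)
    elif fmt == "edf":
        c3, c4, fs, anns = _read_recording_edf(path, aliases or DEFAULT_ALIASES)
    else:
        raise ValueError(f"channel not found: unknown format {fmt!r}")
    if annotations is not None:
        anns = anns + read_annotations_csv(annotations)
    return Recording(subject_id=subject, c3=c3, c4=c4, fs=fs, annotations=anns)


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame({"time_s": t, "c3_uV": rec.c3, "c4_uV": rec.c4}).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_cohort(recordings, ground_truth: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write a synthetic cohort: per-subject signal + annotation CSVs and
    ground_truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in recordings:
        sig = out / f"{rec.subject_id}.csv"
        write_recording_csv(rec, sig)
        write_annotations_csv(rec.annotations, out / f"{rec.subject_id}.events.csv")
        written.append(sig)
    ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return written


def read_cohort(in_dir: str | Path) -> list[Recording]:
    """Read every ``<subject>.csv`` + ``<subject>.events.csv`` pair in a directory."""
    in_dir = Path(in_dir)
    recs = []
    for sig in sorted(in_dir.glob("*.csv")):
        if sig.name.endswith(".events.csv") or sig.name == "ground_truth.csv":
            continue
        events = sig.with_name(f"{sig.stem}.events.csv")
        recs.append(
            read_recording(sig, annotations=events if events.exists() else None)
        )
    if not recs:
        raise ValueError(f"channel not found: no recordings in {in_dir}")
    return recs
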