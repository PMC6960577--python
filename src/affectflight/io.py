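"""CSV persistence for flight sessions (one file per modality per session).

Layout inside a cohort directory, for a session with id ``RC1``:

    RC1_hr.csv        time_s, hr
    RC1_gsr.csv       time_s, gsr
    RC1_eeg.csv       time_s, Fp1 ... T8
    RC1_face.csv      time_s, happy ... scared
    RC1_schedule.csv  task, t_start, t_end
    RC1_latent.csv    (synthetic sessions only)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    EEG_CHANNELS,
    EMOTIONS,
    FlightSession,
    TaskSegment,
    TimeSeries,
)


def save_session(session: FlightSession, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = session.session_id

    def _frame(ts: TimeSeries, columns: list[str]) -> pd.DataFrame:
        vals = ts.values if ts.values.ndim == 2 else ts.values[:, None]
        df = pd.DataFrame(vals, columns=columns)
        df.insert(0, "time_s", ts.timestamps)
        return df

    _frame(session.hr, ["hr"]).to_csv(out / f"{sid}_hr.csv", index=False)
    _frame(session.gsr, ["gsr"]).to_csv(out / f"{sid}_gsr.csv", index=False)
    _frame(session.eeg, list(EEG_CHANNELS)).to_csv(
        out / f"{sid}_eeg.csv", index=False
    )
    _frame(session.face, list(EMOTIONS)).to_csv(
        out / f"{sid}_face.csv", index=False
    )
    pd.DataFrame(
        [
            {"task": s.task_name, "t_start": s.t_start, "t_end": s.t_end}
            for s in session.schedule
        ]
    ).to_csv(out / f"{sid}_schedule.csv", index=False)
    if session.latent is not None:
        _frame(session.latent, list(EMOTIONS)).to_csv(
            out / f"{sid}_latent.csv", index=False
        )


def _load_series(path: Path, modality: str) -> TimeSeries:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    values = df.drop(columns="time_s").to_numpy()
    if values.shape[1] == 1:
        values = values[:, 0]
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return TimeSeries(t, values, float(fs), modality)


def load_session(session_id: str, in_dir) -> FlightSession:
    d = Path(in_dir)
    schedule_df = pd.read_csv(d / f"{session_id}_schedule.csv")
    schedule = [
        TaskSegment(r["task"], r["t_start"], r["t_end"])
        for _, r in schedule_df.iterrows()
    ]
    latent_path = d / f"{session_id}_latent.csv"
    return FlightSession(
        session_id=session_id,
        hr=_load_series(d / f"{session_id}_hr.csv", "hr"),
        gsr=_load_series(d / f"{session_id}_gsr.csv", "gsr"),
        eeg=_load_series(d / f"{session_id}_eeg.csv", "eeg"),
        face=_load_series(d / f"{session_id}_face.csv", "face"),
        schedule=schedule,
        latent=_load_series(latent_path, "latent") if latent_path.exists() else None,
    )


def cohort_ids_in(in_dir) -> list[str]:
    """Session ids that have a complete CSV set in a directory."""
    d = Path(in_dir)
    ids = sorted(p.name[: -len("_hr.csv")] for p in d.glob("*_hr.csv"))
    complete = []
    for sid in ids:
        needed = [f"{sid}_{m}.csv" for m in ("gsr", "eeg", "face", "schedule")]
        if all((d / n).exists() for n in needed):
            complete.append(sid)
    return complete


def save_cohort(cohort: list[FlightSession], out_dir) -> None:
    for session in cohort:
        save_session(session, out_dir)


def load_cohort(in_dir) -> list[FlightSession]:
    return [load_session(sid, in_dir) for sid in cohort_ids_in(in_dir)]
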