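"""Tidy-text import/export: sessions, belief trajectories, evidence matrices, BMS results.

Sessions and trajectories are stored as tab-separated tables with one row per
trial; the evidence matrix as a subjects x models TSV; BMS results as JSON.
User-supplied behavioural data can be loaded from the same session format
(columns: trial, choice, correct, blame, rt, mood, plus the generative
schedule columns when available).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bms import BMSResult
from .hgf import BeliefTrajectory
from .task import ScheduleConfig, Session, TaskSchedule

__all__ = [
    "session_to_frame",
    "frame_to_session",
    "save_sessions",
    "load_sessions",
    "trajectory_to_frame",
    "save_evidence",
    "load_evidence",
    "bms_to_json",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    """One row per trial, including the generative schedule columns."""
    sch = session.schedule
    return pd.DataFrame(
        {
            "trial": np.arange(1, session.n_trials + 1),
            "choice": session.choice,
            "correct": session.correct,
            "blame": session.blame,
            "rt": session.rt,
            "mood": session.mood,
            "p_correct_cue1": sch.p_correct_cue1,
            "p_blame_given_wrong": sch.p_blame_given_wrong,
            "good_cue": sch.good_cue,
            "blame_block": sch.blame_block_label,
            "is_reversal_start": sch.is_reversal_start.astype(int),
            "mood_probe": sch.mood_probe.astype(int),
        }
    )


def frame_to_session(
    df: pd.DataFrame,
    subject_id: str,
    config: ScheduleConfig | None = None,
) -> Session:
    """Rebuild a session (and its schedule) from a per-trial table."""
    n = len(df)
    if config is None:
        config = ScheduleConfig(n_trials=n)
    schedule = TaskSchedule(
        config=config,
        p_correct_cue1=df["p_correct_cue1"].to_numpy(dtype=float),
        p_blame_given_wrong=df["p_blame_given_wrong"].to_numpy(dtype=float),
        good_cue=df["good_cue"].to_numpy(dtype=np.int64),
        blame_block_label=df["blame_block"].to_numpy(dtype="U4"),
        is_reversal_start=df["is_reversal_start"].to_numpy(dtype=bool),
        mood_probe=df["mood_probe"].to_numpy(dtype=bool),
    )
    return Session(
        subject_id=subject_id,
        schedule=schedule,
        choice=df["choice"].to_numpy(dtype=np.int64),
        correct=df["correct"].to_numpy(dtype=np.int64),
        blame=df["blame"].to_numpy(dtype=np.int64),
        rt=df["rt"].to_numpy(dtype=float),
        mood=df["mood"].to_numpy(dtype=float),
    )


def save_sessions(sessions: Sequence[Session], out_dir: str | Path) -> list[Path]:
    """Write one TSV per session plus a JSON manifest; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for s in sessions:
        p = out / f"{s.subject_id}.tsv"
        session_to_frame(s).to_csv(p, sep="\t", index=False, na_rep="NA")
        cfg = s.schedule.config
        manifest.append(
            {"subject_id": s.subject_id, "file": p.name, "n_trials": cfg.n_trials,
             "mood_probe_period": cfg.mood_probe_period}
        )
        paths.append(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def load_sessions(in_dir: str | Path) -> list[Session]:
    """Load every session listed in a directory's manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    sessions = []
    for entry in manifest:
        df = pd.read_csv(in_dir / entry["file"], sep="\t", na_values="NA")
        cfg = ScheduleConfig(
            n_trials=entry["n_trials"], mood_probe_period=entry["mood_probe_period"]
        )
        sessions.append(frame_to_session(df, entry["subject_id"], config=cfg))
    return sessions


def trajectory_to_frame(traj: BeliefTrajectory) -> pd.DataFrame:
    """One row per trial: predictions, uncertainty, blame belief and BPE."""
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(traj) + 1),
            "muhat1": traj.muhat1,
            "sigmahat2": traj.sigmahat2,
            "pblame": traj.pblame,
            "delta_blame": traj.delta_blame,
            "mu2": traj.mu2,
            "mu3": traj.mu3,
            "sigma2": traj.sigma2,
            "sigma3": traj.sigma3,
        }
    )


def save_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t")


def load_evidence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def bms_to_json(result: BMSResult, path: str | Path, seed: int | None = None) -> None:
    """Serialize a BMS result (with the RNG seed used for the EP sampling)."""
    payload = {
        "model_names": result.model_names,
        "alpha": result.alpha.tolist(),
        "r": result.r.tolist(),
        "ep": result.ep.tolist(),
        "bor": result.bor,
        "pep": result.pep.tolist(),
        "best_model": result.best_model,
        "ep_seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
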