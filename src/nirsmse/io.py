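"""Long-format session CSV reading/writing.

Columns: participant_id, medium, channel, phase{rest|task}, sample_index,
value, fatigue_score. ``sample_index`` is 0-based within each phase; the
fatigue cell may be empty (missing self-report). Write-then-read is the
identity up to float text precision.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import NirsSession

__all__ = ["SessionParseError", "read_sessions", "write_sessions", "SESSION_COLUMNS"]

SESSION_COLUMNS = (
    "participant_id", "medium", "channel", "phase",
    "sample_index", "value", "fatigue_score",
)


class SessionParseError(ValueError):
    """Malformed session CSV."""


def write_sessions(sessions: Sequence[NirsSession], path: str | Path, fs_check: bool = True) -> None:
    """Write sessions to the long-format CSV (deterministic row order)."""
    path = Path(path)
    frames = []
    for s in sessions:
        for phase, mat in (("rest", s.rest), ("task", s.task)):
            n = mat.shape[1]
            for ci, ch in enumerate(s.channel_labels):
                frames.append(pd.DataFrame({
                    "participant_id": s.participant_id,
                    "medium": s.medium,
                    "channel": ch,
                    "phase": phase,
                    "sample_index": np.arange(n),
                    "value": mat[ci],
                    "fatigue_score": "" if s.fatigue_score is None else s.fatigue_score,
                }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(SESSION_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def read_sessions(path: str | Path, sampling_rate_hz: float = 10.0) -> list[NirsSession]:
    """Read sessions from the long-format CSV.

    The carrier format does not store the sampling rate; supply it via
    ``sampling_rate_hz``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str, "medium": str,
                                      "channel": str, "phase": str})
    except pd.errors.EmptyDataError:
        raise SessionParseError(f"{path}: file is empty (expected a header)")
    if tuple(df.columns) != SESSION_COLUMNS:
        raise SessionParseError(
            f"{path}: malformed header {list(df.columns)}; expected {list(SESSION_COLUMNS)}"
        )
    if df.empty:
        return []
    bad_phase = ~df["phase"].isin(["rest", "task"])
    if bad_phase.any():
        row = int(df.index[bad_phase][0]) + 2  # 1-based, counting the header
        raise SessionParseError(f"{path}: row {row}: phase must be 'rest' or 'task'")

    sessions: list[NirsSession] = []
    # preserve first-appearance order of sessions and channels
    for (pid, medium), g in df.groupby(["participant_id", "medium"], sort=False):
        channels = list(dict.fromkeys(g["channel"]))
        fat_vals = g["fatigue_score"].dropna().unique()
        if len(fat_vals) > 1:
            raise SessionParseError(
                f"{path}: session ({pid}, {medium}) has inconsistent fatigue scores"
            )
        fatigue = None if len(fat_vals) == 0 else int(fat_vals[0])
        mats: dict[str, np.ndarray] = {}
        for phase in ("rest", "task"):
            gp = g[g["phase"] == phase]
            if gp.empty:
                raise SessionParseError(
                    f"{path}: session ({pid}, {medium}) is missing its {phase} segment"
                )
            per_channel = []
            length = None
            for ch in channels:
                gc = gp[gp["channel"] == ch]
                if gc.empty:
                    row = int(gp.index[0]) + 2
                    raise SessionParseError(
                        f"{path}: row {row}: channel {ch} absent from {phase} "
                        f"segment of session ({pid}, {medium})"
                    )
                idx = gc["sample_index"].to_numpy()
                if not np.array_equal(idx, np.arange(len(idx))):
                    row = int(gc.index[0]) + 2
                    raise SessionParseError(
                        f"{path}: row {row}: sample_index not 0..n-1 monotone for "
                        f"({pid}, {medium}, {ch}, {phase})"
                    )
                if length is None:
                    length = len(idx)
                elif len(idx) != length:
                    row = int(gc.index[0]) + 2
                    raise SessionParseError(
                        f"{path}: row {row}: inconsistent channel lengths in "
                        f"({pid}, {medium}, {phase})"
                    )
                per_channel.append(gc["value"].to_numpy(dtype=np.float64))
            mats[phase] = np.vstack(per_channel)
        if mats["rest"].shape[0] != mats["task"].shape[0]:
            raise SessionParseError(
                f"{path}: session ({pid}, {medium}) has inconsistent channels "
                "between rest and task"
            )
        sessions.append(NirsSession(
            participant_id=str(pid),
            medium=str(medium),
            sampling_rate_hz=sampling_rate_hz,
            channel_labels=tuple(channels),
            rest=mats["rest"],
            task=mats["task"],
            fatigue_score=fatigue,
        ))
    return sessions
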