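"""Core data containers for the fTCD laterality pipeline.

The pipeline moves through three canonical objects:

``CBFVRecording``
    A raw bilateral cerebral-blood-flow-velocity recording (left and right
    middle cerebral artery channels) with trial-onset markers.

``EpochSet``
    Per-trial peri-stimulus matrices cut around each marker, carrying
    usable/rejected flags with a single primary rejection reason per trial.

``LITable``
    The participants x indicators table of laterality indices (tasks A-F at
    sessions 1 and 2), with handedness group and testing-site labels, missing
    cells and per-cell usable-trial counts.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TASKS: list[str] = list("ABCDEF")
SESSIONS: tuple[int, int] = (1, 2)
#: Canonical indicator order: session 1 tasks A-F, then session 2 tasks A-F.
INDICATORS: list[str] = [f"{t}{s}" for s in SESSIONS for t in TASKS]
#: Marker (reference) indicator task: Sentence Generation.
MARKER_TASK: str = "D"

#: Valid primary rejection reasons for an unusable trial.
REJECTION_REASONS = (
    "range-artifact",
    "manual",
    "extreme-value",
    "no-response",
    "no-heartbeat",
)


@dataclass
class CBFVRecording:
    """Bilateral CBFV time series with trial-onset markers.

    Velocities are in arbitrary positive units until normalization; time in
    seconds. ``marker_times`` are trial-onset times, strictly increasing.
    """

    fs: float
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    marker_times: np.ndarray
    subject: str = ""
    task: str = ""
    session: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.marker_times = np.asarray(self.marker_times, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.time)
        if len(self.left) != n or len(self.right) != n:
            raise ValueError("time, left and right series must have equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("velocities must be finite")
        if np.any(np.diff(self.marker_times) <= 0):
            raise ValueError("marker times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) else 0.0

    def copy(self) -> "CBFVRecording":
        return CBFVRecording(
            fs=self.fs,
            time=self.time.copy(),
            left=self.left.copy(),
            right=self.right.copy(),
            marker_times=self.marker_times.copy(),
            subject=self.subject,
            task=self.task,
            session=self.session,
        )

    # -- tab-delimited exchange format: time_s, left, right, marker ---------
    def to_tsv(self, path) -> None:
        marker = np.zeros(len(self.time), dtype=int)
        if len(self.marker_times):
            idx = np.searchsorted(self.time, self.marker_times)
            idx = np.clip(idx, 0, len(self.time) - 1)
            # snap to nearest sample
            for k, t in zip(idx.copy(), self.marker_times):
                if k > 0 and abs(self.time[k - 1] - t) < abs(self.time[k] - t):
                    k -= 1
                marker[k] = 1
        df = pd.DataFrame(
            {"time_s": self.time, "left": self.left, "right": self.right, "marker": marker}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, subject: str = "", task: str = "", session: int = 1) -> "CBFVRecording":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("recording too short")
        fs = round(1.0 / float(np.median(np.diff(t))), 6)
        onsets = t[df["marker"].to_numpy() > 0]
        return cls(
            fs=fs,
            time=t,
            left=df["left"].to_numpy(float),
            right=df["right"].to_numpy(float),
            marker_times=onsets,
            subject=subject,
            task=task,
            session=session,
        )


@dataclass
class EpochSet:
    """Per-trial peri-stimulus matrices with usable flags and QC metadata.

    ``times`` is the peri-stimulus axis (seconds relative to trial onset);
    ``left``/``right`` are ``(n_trials, n_samples)``; ``onsets`` holds each
    trial's absolute onset time in the source recording. ``channel_stats``
    carries recording-wide raw means/SDs (used by range rejection and
    normalization), and the processing-state booleans record which pipeline
    stages have been applied.
    """

    times: np.ndarray
    fs: float
    left: np.ndarray
    right: np.ndarray
    onsets: np.ndarray
    usable: np.ndarray
    reasons: list[Optional[str]]
    channel_stats: dict = field(default_factory=dict)
    beats: Optional[np.ndarray] = None
    normalized: bool = False
    integrated: bool = False
    baselined: bool = False
    baseline_means: Optional[np.ndarray] = None  # (n_trials, 2) added back for QC
    subject: str = ""
    task: str = ""
    session: int = 1

    @property
    def n_trials(self) -> int:
        return int(self.left.shape[0])

    @property
    def n_usable(self) -> int:
        return int(np.sum(self.usable))

    def copy(self) -> "EpochSet":
        return dataclasses.replace(
            self,
            times=self.times.copy(),
            left=self.left.copy(),
            right=self.right.copy(),
            onsets=self.onsets.copy(),
            usable=self.usable.copy(),
            reasons=list(self.reasons),
            channel_stats=dict(self.channel_stats),
            beats=None if self.beats is None else self.beats.copy(),
            baseline_means=None if self.baseline_means is None else self.baseline_means.copy(),
        )

    def flag(self, trial: int, reason: str) -> None:
        """Mark a trial unusable with its primary reason (first reason wins)."""
        if reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        if self.usable[trial]:
            self.usable[trial] = False
            self.reasons[trial] = reason

    # -- archive: per-trial CSVs plus a JSON sidecar -------------------------
    def save(self, path) -> None:
        sidecar = {
            "fs": self.fs,
            "times": self.times.tolist(),
            "onsets": self.onsets.tolist(),
            "usable": self.usable.astype(bool).tolist(),
            "reasons": self.reasons,
            "channel_stats": self.channel_stats,
            "beats": None if self.beats is None else self.beats.tolist(),
            "normalized": self.normalized,
            "integrated": self.integrated,
            "baselined": self.baselined,
            "subject": self.subject,
            "task": self.task,
            "session": self.session,
        }
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("epochs.json", json.dumps(sidecar))
            for i in range(self.n_trials):
                buf = io.StringIO()
                pd.DataFrame(
                    {"peristim_s": self.times, "left": self.left[i], "right": self.right[i]}
                ).to_csv(buf, index=False)
                zf.writestr(f"trial_{i:03d}.csv", buf.getvalue())

    @classmethod
    def load(cls, path) -> "EpochSet":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("epochs.json"))
            trials = sorted(n for n in zf.namelist() if n.startswith("trial_"))
            left, right = [], []
            for name in trials:
                df = pd.read_csv(io.BytesIO(zf.read(name)))
                left.append(df["left"].to_numpy(float))
                right.append(df["right"].to_numpy(float))
        return cls(
            times=np.asarray(meta["times"], float),
            fs=float(meta["fs"]),
            left=np.asarray(left, float),
            right=np.asarray(right, float),
            onsets=np.asarray(meta["onsets"], float),
            usable=np.asarray(meta["usable"], bool),
            reasons=[r for r in meta["reasons"]],
            channel_stats=meta["channel_stats"],
            beats=None if meta["beats"] is None else np.asarray(meta["beats"], float),
            normalized=meta["normalized"],
            integrated=meta["integrated"],
            baselined=meta["baselined"],
            subject=meta["subject"],
            task=meta["task"],
            session=meta["session"],
        )


class LITable:
    """Participants x indicators laterality-index table.

    ``data`` is a DataFrame indexed by subject id with columns ``group``,
    ``site`` and the 12 indicators (NaN = missing). ``counts`` optionally
    holds per-cell usable-trial counts; ``reasons`` maps
    ``(subject, indicator)`` to the exclusion reason for quality-missing
    cells.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        counts: Optional[pd.DataFrame] = None,
        reasons: Optional[dict] = None,
    ):
        missing_cols = [c for c in ("group", "site") if c not in data.columns]
        if missing_cols:
            raise ValueError(f"LITable missing columns: {missing_cols}")
        for ind in INDICATORS:
            if ind not in data.columns:
                raise ValueError(f"LITable missing indicator column {ind}")
        bad = set(data["group"]) - {"left", "right"}
        if bad:
            raise ValueError(f"handedness group must be 'left' or 'right', got {bad}")
        self.data = data.loc[:, ["group", "site"] + INDICATORS].copy()
        self.counts = counts.loc[:, INDICATORS].copy() if counts is not None else None
        self.reasons = dict(reasons) if reasons else {}

    # ------------------------------------------------------------------ api
    @property
    def subjects(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> pd.DataFrame:
        """Indicator values only (subjects x 12), NaN for missing."""
        return self.data[INDICATORS]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.data.loc[self.data["group"] == group, INDICATORS]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def n_observed_cells(self) -> int:
        return int(self.values.notna().sum().sum())

    def copy(self) -> "LITable":
        return LITable(
            self.data.copy(),
            None if self.counts is None else self.counts.copy(),
            dict(self.reasons),
        )

    def session_means(self) -> pd.DataFrame:
        """Per-task LI averaged over sessions, ignoring missing cells."""
        out = {}
        for t in TASKS:
            out[t] = self.data[[f"{t}1", f"{t}2"]].mean(axis=1)
        return pd.DataFrame(out, index=self.data.index)

    # ------------------------------------------------------------------- io
    def to_csv(self, path) -> None:
        df = self.data.reset_index().rename(columns={"index": "subject"})
        if df.columns[0] != "subject":
            df = df.rename(columns={df.columns[0]: "subject"})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, counts_path=None) -> "LITable":
        df = pd.read_csv(path)
        df = df.set_index("subject")
        counts = None
        if counts_path is not None:
            counts = pd.read_csv(counts_path).set_index("subject")
        return cls(df, counts=counts)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LITable({len(self.data)} participants, "
            f"{self.n_observed_cells()}/{12 * len(self.data)} cells observed)"
        )
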