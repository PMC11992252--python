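"""Session container, cross-session cell registry, and HDF5 / CSV persistence.

One :class:`SessionData` holds everything recorded in a single imaging
session: ΔF/F traces, the animal's position and running velocity per frame,
lick and reward event frames, and trial boundaries. Sessions round-trip
losslessly through a documented HDF5 layout::

    /dff                      float32, neurons x frames
    /behavior/position_cm     float per frame
    /behavior/velocity_cm_s   float per frame
    /events/lick_frames       int
    /events/reward_frames     int
    /trials                   n_trials x 2 int (start, end), half-open
    attrs: mouse_id, day, frame_rate_hz
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .corridor import phase_of_day

__all__ = [
    "SessionData",
    "CellRegistry",
    "SchemaError",
    "ValidationError",
    "load_session",
    "save_session",
    "save_results",
]


class SchemaError(Exception):
    """A required dataset or attribute is missing from the container."""


class ValidationError(Exception):
    """An invariant of the session container is violated."""


@dataclass
class SessionData:
    """One imaging session: traces, behaviour, trial structure, metadata."""

    dff: np.ndarray               # neurons x frames, ΔF/F
    position_cm: np.ndarray       # per frame
    velocity_cm_s: np.ndarray     # per frame
    lick_frames: np.ndarray       # sorted int frame indices
    reward_frames: np.ndarray     # sorted int frame indices
    trial_bounds: np.ndarray      # n_trials x 2, half-open [start, end)
    day: int = 0                  # relative to injection day
    mouse_id: str = "sim"
    frame_rate_hz: float = 30.0

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=np.float64)
        self.position_cm = np.asarray(self.position_cm, dtype=np.float64)
        self.velocity_cm_s = np.asarray(self.velocity_cm_s, dtype=np.float64)
        self.lick_frames = np.asarray(self.lick_frames, dtype=np.int64)
        self.reward_frames = np.asarray(self.reward_frames, dtype=np.int64)
        self.trial_bounds = np.asarray(self.trial_bounds, dtype=np.int64).reshape(-1, 2)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_frames = self.dff.shape[1]
        if self.dff.ndim != 2:
            raise ValidationError("dff must be a neurons x frames matrix")
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("dff contains missing or non-finite values")
        for name in ("position_cm", "velocity_cm_s"):
            v = getattr(self, name)
            if v.shape != (n_frames,):
                raise ValidationError(
                    f"{name} has length {v.shape}, expected ({n_frames},)"
                )
        for name in ("lick_frames", "reward_frames"):
            v = getattr(self, name)
            if v.size and (v.min() < 0 or v.max() >= n_frames):
                raise ValidationError(f"{name} contains out-of-range frame indices")
            if v.size and np.any(np.diff(v) < 0):
                raise ValidationError(f"{name} must be sorted")
        tb = self.trial_bounds
        if tb.size:
            if np.any(tb[:, 0] >= tb[:, 1]):
                raise ValidationError("trial_bounds must be non-empty half-open intervals")
            if tb.min() < 0 or tb.max() > n_frames:
                raise ValidationError("trial_bounds exceed the recording")
            if np.any(tb[1:, 0] < tb[:-1, 1]):
                raise ValidationError("trial_bounds overlap or are unordered")

    # -- convenience ------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def n_trials(self) -> int:
        return self.trial_bounds.shape[0]

    @property
    def phase(self) -> str:
        return phase_of_day(self.day)

    def trial_of_frame(self) -> np.ndarray:
        """Trial index per frame; -1 for frames outside any trial (blackout).

        Frames outside trial bounds are excluded from every analysis.
        """
        trial = np.full(self.n_frames, -1, dtype=np.int64)
        for k, (a, b) in enumerate(self.trial_bounds):
            trial[a:b] = k
        return trial


def save_session(session: SessionData, path) -> None:
    """Write a session to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=session.dff.astype(np.float32))
        beh = f.create_group("behavior")
        beh.create_dataset("position_cm", data=session.position_cm)
        beh.create_dataset("velocity_cm_s", data=session.velocity_cm_s)
        ev = f.create_group("events")
        ev.create_dataset("lick_frames", data=session.lick_frames)
        ev.create_dataset("reward_frames", data=session.reward_frames)
        f.create_dataset("trials", data=session.trial_bounds)
        f.attrs["mouse_id"] = session.mouse_id
        f.attrs["day"] = int(session.day)
        f.attrs["frame_rate_hz"] = float(session.frame_rate_hz)


_REQUIRED = ["dff", "behavior/position_cm", "behavior/velocity_cm_s",
             "events/lick_frames", "events/reward_frames", "trials"]


def load_session(path) -> SessionData:
    """Load and validate a session from its HDF5 container.

    Raises :class:`SchemaError` when a dataset is missing and
    :class:`ValidationError` (naming the field) when an invariant fails.
    """
    with h5py.File(path, "r") as f:
        for key in _REQUIRED:
            if key not in f:
                raise SchemaError(f"dataset '{key}' missing from {path}")
        return SessionData(
            dff=f["dff"][()].astype(np.float64),
            position_cm=f["behavior/position_cm"][()],
            velocity_cm_s=f["behavior/velocity_cm_s"][()],
            lick_frames=f["events/lick_frames"][()],
            reward_frames=f["events/reward_frames"][()],
            trial_bounds=f["trials"][()],
            mouse_id=str(f.attrs.get("mouse_id", "unknown")),
            day=int(f.attrs.get("day", 0)),
            frame_rate_hz=float(f.attrs.get("frame_rate_hz", 30.0)),
        )


@dataclass
class CellRegistry:
    """Cross-session neuron identity table with per-phase class labels.

    ``table`` maps tracked neuron uid (row) -> session id (column) -> ROI
    index, with -1 for absent. ``class_by_phase`` maps phase -> label per
    neuron, labels in {stable_pc, unstable_pc, noncoding, absent}.
    """

    table: pd.DataFrame
    class_by_phase: pd.DataFrame | None = None

    def __post_init__(self):
        t = self.table
        for col in t.columns:
            vals = t[col].to_numpy()
            present = vals[vals >= 0]
            if len(np.unique(present)) != len(present):
                raise ValidationError(
                    f"session {col}: a ROI is claimed by more than one neuron"
                )

    @property
    def neuron_uids(self):
        return self.table.index.to_numpy()

    def roi_index(self, uid, session_id) -> int:
        return int(self.table.loc[uid, session_id])

    def present_in(self, session_ids) -> np.ndarray:
        """uids of neurons present (roi >= 0) in every listed session."""
        sub = self.table[list(session_ids)]
        return sub.index[(sub >= 0).all(axis=1)].to_numpy()

    def to_csv(self, path) -> None:
        long = self.table.stack().rename("roi_index").reset_index()
        long.columns = ["neuron_uid", "session_id", "roi_index"]
        long = long[long.roi_index >= 0]
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellRegistry":
        long = pd.read_csv(path)
        table = long.pivot(index="neuron_uid", columns="session_id",
                           values="roi_index").fillna(-1).astype(int)
        table.columns.name = None
        return cls(table=table)


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_results(tables: dict[str, pd.DataFrame], path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Write result tables as CSVs plus a JSON run manifest.

    Reruns with the same config and seed produce byte-identical CSVs; the
    manifest records the config hash, seed and library versions for audit.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        pd.DataFrame(df).to_csv(p, index=False)
        written.append(p.name)
    manifest = {
        "tables": sorted(written),
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
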