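"""Trial containers and HDF5 serialization.

A :class:`SyntheticDataset` is the package's stand-in for a multi-subject
MEG recording session: per subject, a NaN-padded array of continuous trial
segments (trial x sensor x sample), a gaze trace on the same time base, and
a trial table with condition labels, behavior and ground-truth effect sizes.

Time convention: sample 0 of every trial corresponds to t = -1 s relative
to cue onset; a trial with pre-target period ``T`` is valid up to
t = T + 1 s.  Samples beyond a trial's length are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .layout import SensorArray, make_sensor_array

__all__ = ["SubjectData", "SyntheticDataset", "TRIAL_COLUMNS", "save_dataset", "load_dataset"]

#: canonical column order of the per-subject trial table
TRIAL_COLUMNS = [
    "trial",
    "difficulty",
    "eccentricity",
    "hemifield",
    "pre_target_period",
    "correct",
    "rt",
    "true_effect",
]

#: time of the first sample of every trial, s relative to cue onset
T_START = -1.0


@dataclass
class SubjectData:
    """One subject's trials.

    ``data`` has shape (n_trials, n_sensors, n_samples_max), float32, with
    NaN padding beyond each trial's own length; ``gaze`` has shape
    (n_trials, 2, n_samples_max) in degrees of visual angle (x, y).
    """

    subject: str
    trials: pd.DataFrame
    data: np.ndarray
    gaze: np.ndarray
    fs: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def n_samples(self, i: int) -> int:
        """Valid sample count of trial ``i`` (rest of the row is padding)."""
        t = float(self.trials["pre_target_period"].iloc[i])
        return int(round((t + 1.0 - T_START) * self.fs))

    def times(self) -> np.ndarray:
        """Time axis of the padded sample dimension, s relative to cue."""
        return T_START + np.arange(self.data.shape[-1]) / self.fs

    def select(self, idx: np.ndarray) -> "SubjectData":
        """Subset of trials (keeps chronological order of ``idx``)."""
        idx = np.asarray(idx)
        return SubjectData(
            subject=self.subject,
            trials=self.trials.iloc[idx].reset_index(drop=True),
            data=self.data[idx],
            gaze=self.gaze[idx],
            fs=self.fs,
        )


@dataclass
class SyntheticDataset:
    """Multi-subject collection plus the sensor layout that produced it."""

    sensors: SensorArray
    subjects: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list:
        return [s.subject for s in self.subjects]

    def map_subjects(self, fn) -> "SyntheticDataset":
        return replace(self, subjects=[fn(s) for s in self.subjects])

    def trials_table(self) -> pd.DataFrame:
        """All subjects' trial tables stacked, with a ``subject`` column."""
        parts = []
        for s in self.subjects:
            t = s.trials.copy()
            t.insert(0, "subject", s.subject)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)


def save_dataset(dataset: SyntheticDataset, path) -> None:
    """Write a dataset to an HDF5 file (one group per subject)."""
    with h5py.File(path, "w") as f:
        lay = dataset.sensors.to_frame()
        grp = f.create_group("sensors")
        grp.create_dataset("label", data=np.array(lay["label"], dtype="S16"))
        grp.create_dataset("x", data=lay["x"].to_numpy())
        grp.create_dataset("y", data=lay["y"].to_numpy())
        grp.create_dataset("hemisphere", data=np.array(lay["hemisphere"], dtype="S1"))
        for key, val in dataset.meta.items():
            f.attrs[key] = val
        for s in dataset.subjects:
            g = f.create_group(f"subjects/{s.subject}")
            g.attrs["fs"] = s.fs
            g.create_dataset("data", data=s.data, compression="gzip", compression_opts=1)
            g.create_dataset("gaze", data=s.gaze, compression="gzip", compression_opts=1)
            tg = g.create_group("trials")
            for col in s.trials.columns:
                v = s.trials[col].to_numpy()
                if v.dtype == object:
                    v = v.astype("S16")
                tg.create_dataset(col, data=v)


def load_dataset(path) -> SyntheticDataset:
    """Inverse of :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        labels = [x.decode() for x in f["sensors/label"][()]]
        # reconstruct the layout from its size; verify geometry round-trips
        sensors = make_sensor_array(len(labels))
        assert list(sensors.labels) == labels, "layout mismatch on load"
        meta = dict(f.attrs)
        subjects = []
        for name in sorted(f["subjects"], key=lambda s: (len(s), s)):
            g = f[f"subjects/{name}"]
            cols = {}
            for col in g["trials"]:
                v = g["trials"][col][()]
                if v.dtype.kind == "S":
                    v = np.array([x.decode() for x in v], dtype=object)
                cols[col] = v
            trials = pd.DataFrame(cols)
            order = [c for c in TRIAL_COLUMNS if c in trials.columns]
            order += [c for c in trials.columns if c not in order]
            subjects.append(
                SubjectData(
                    subject=name,
                    trials=trials[order],
                    data=g["data"][()],
                    gaze=g["gaze"][()],
                    fs=float(g.attrs["fs"]),
                )
            )
    return SyntheticDataset(sensors=sensors, subjects=subjects, meta=meta)
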