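"""The multivariate functional-trial container and its on-disk formats.

A :class:`FunctionalTrialSet` holds an ``n x J x F`` tensor of synchronized
functional trajectories on a shared time grid, per-trial class labels in
{0, 1, 2}, and a padding mask marking which grid points were actually
observed (trials shorter than J are zero-padded at the tail; the padded
curves are integrated as-is, the mask exists for diagnostics).

Two interchangeable storage formats are provided: a plain-text directory
(one tab-separated J x F matrix per trial plus a JSON manifest) and a
single-file compressed ``.npz``; both readers validate the same invariants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import TimeGrid, make_time_grid

__all__ = [
    "FunctionalTrialSet",
    "save_trialset_text",
    "load_trialset_text",
    "save_trialset_npz",
    "load_trialset_npz",
]

N_CLASSES = 3


@dataclass
class FunctionalTrialSet:
    """n trials x J timepoints x F channels on a shared [0,1] grid."""

    values: np.ndarray
    grid: TimeGrid
    labels: np.ndarray
    pad_mask: np.ndarray = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be an n x J x F tensor")
        n, J, F = self.values.shape
        if F < 1:
            raise ValueError("at least one channel is required")
        if J != self.grid.J:
            raise ValueError(f"values have J={J} but grid has J={self.grid.J}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (n,):
            raise ValueError("labels must be one integer per trial")
        if not np.isin(self.labels, np.arange(N_CLASSES)).all():
            raise ValueError("labels must lie in {0, 1, 2}")
        if self.pad_mask is None:
            self.pad_mask = np.ones((n, J), dtype=bool)
        self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
        if self.pad_mask.shape != (n, J):
            raise ValueError("pad_mask must be n x J")
        if not self.pad_mask.any(axis=1).all():
            raise ValueError("every trial needs at least one observed point")
        if np.any(self.values[~self.pad_mask] != 0.0):
            raise ValueError("padded entries must be exactly zero")
        if not self.channel_names:
            self.channel_names = [f"ch{f}" for f in range(F)]
        if len(self.channel_names) != F:
            raise ValueError("need one channel name per channel")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def F(self) -> int:
        return self.values.shape[2]

    def subset(self, idx) -> "FunctionalTrialSet":
        idx = np.asarray(idx)
        return FunctionalTrialSet(
            self.values[idx],
            self.grid,
            self.labels[idx],
            self.pad_mask[idx],
            list(self.channel_names),
        )

    def select_channels(self, channels) -> "FunctionalTrialSet":
        channels = list(channels)
        return FunctionalTrialSet(
            self.values[:, :, channels],
            self.grid,
            self.labels,
            self.pad_mask,
            [self.channel_names[c] for c in channels],
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLASSES)


# -- text directory format -------------------------------------------------


def save_trialset_text(ts: FunctionalTrialSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n": ts.n,
        "J": ts.grid.J,
        "channel_names": ts.channel_names,
        "labels": ts.labels.tolist(),
        "observed_lengths": ts.pad_mask.sum(axis=1).tolist(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for i in range(ts.n):
        np.savetxt(d / f"trial_{i:04d}.tsv", ts.values[i], delimiter="\t")


def load_trialset_text(directory) -> FunctionalTrialSet:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    n, J = manifest["n"], manifest["J"]
    values = np.stack(
        [
            np.loadtxt(d / f"trial_{i:04d}.tsv", delimiter="\t", ndmin=2)
            for i in range(n)
        ]
    )
    mask = np.zeros((n, J), dtype=bool)
    for i, L in enumerate(manifest["observed_lengths"]):
        mask[i, :L] = True
    return FunctionalTrialSet(
        values, make_time_grid(J), manifest["labels"], mask, manifest["channel_names"]
    )


# -- npz format ------------------------------------------------------------


def save_trialset_npz(ts: FunctionalTrialSet, path) -> None:
    np.savez_compressed(
        path,
        values=ts.values,
        labels=ts.labels,
        pad_mask=ts.pad_mask,
        channel_names=np.array(ts.channel_names),
        grid_points=ts.grid.points,
    )


def load_trialset_npz(path) -> FunctionalTrialSet:
    with np.load(path, allow_pickle=False) as z:
        return FunctionalTrialSet(
            z["values"],
            TimeGrid(z["grid_points"]),
            z["labels"],
            z["pad_mask"],
            [str(c) for c in z["channel_names"]],
        )
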