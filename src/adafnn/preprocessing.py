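"""Raw landmark and biosignal streams -> synchronized functional tensors.

The upstream data are (i) per-frame facial-landmark coordinates at 30 fps
and (ii) two-channel biosignal recordings (ECG, EDA) at 300 Hz.  Facial
motion is quantified as the Euclidean displacement of each landmark between
consecutive frames; biosignals are synchronized to the video frame rate by
averaging every ten consecutive samples (a moving-average downsample that
also attenuates high-frequency noise).  Trials shorter than the reference
length are zero-padded at the tail.  Five dataset configurations assemble
the channels: facial only, bio only, full fusion, a selected-landmark
subset, and that subset plus the biosignals.

Outliers are screened with Tukey fences (1.5 IQR beyond the quartiles) but
only *flagged* — exclusion is an explicit user action via a trial
blacklist, mirroring a manual review step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FunctionalTrialSet
from .grid import make_time_grid

__all__ = [
    "LandmarkFrameSeries",
    "BioSignalRecording",
    "DatasetConfiguration",
    "CONFIGURATION_IDS",
    "landmark_displacement_series",
    "downsample_moving_average",
    "pad_trials",
    "tukey_outlier_flags",
    "assemble_configuration",
    "read_biosignal_file",
    "read_landmark_file",
]

CONFIGURATION_IDS = (
    "facial_only",
    "bio_only",
    "full_fusion",
    "selected_facial",
    "selected_facial_plus_bio",
)


@dataclass(frozen=True)
class LandmarkFrameSeries:
    """T frames x L landmarks x (x, y) coordinates, 30 fps."""

    coords: np.ndarray
    fps: float = 30.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 3 or c.shape[2] != 2 or c.shape[0] < 2 or c.shape[1] < 1:
            raise ValueError("coords must be T x L x 2 with T >= 2, L >= 1")
        if not np.isfinite(c).all():
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class BioSignalRecording:
    """M samples x 2 channels (ECG, EDA) at ``rate`` Hz (300 by default)."""

    samples: np.ndarray
    rate: float = 300.0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != 2:
            raise ValueError("samples must be M x 2 (ECG, EDA)")
        if s.shape[0] < self.rate / 30.0:
            raise ValueError("recording too short to yield one output sample")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class DatasetConfiguration:
    id: str
    selected_indices: tuple | None = None

    def __post_init__(self):
        if self.id not in CONFIGURATION_IDS:
            raise ValueError(f"unknown configuration id {self.id!r}")
        if self.id.startswith("selected") and not self.selected_indices:
            raise ValueError(f"{self.id} requires non-empty selected_indices")


def landmark_displacement_series(frames: LandmarkFrameSeries) -> np.ndarray:
    """Euclidean distance of each landmark between consecutive frames,
    a (T-1) x L matrix of non-negative displacements."""
    c = frames.coords
    return np.linalg.norm(np.diff(c, axis=0), axis=2)


def downsample_moving_average(recording, factor: int) -> np.ndarray:
    """Average every ``factor`` consecutive samples per channel (factor=10
    maps 300 Hz onto the 30 fps video rate); leftover samples beyond the
    last full window are dropped."""
    if isinstance(recording, BioSignalRecording):
        x = recording.samples
    else:
        x = np.asarray(recording, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    M, C = x.shape
    if M < factor:
        raise ValueError(f"need at least factor={factor} samples, got {M}")
    n_out = M // factor
    out = x[: n_out * factor].reshape(n_out, factor, C).mean(axis=1)
    return out[:, 0] if squeeze else out


def pad_trials(trials: list[np.ndarray], target_J: int):
    """Zero-pad ragged J_i x F trials at the tail to a common length.

    Returns (values, pad_mask) with values of shape n x target_J x F and the
    mask false exactly on appended rows.
    """
    trials = [np.atleast_2d(np.asarray(tr, dtype=np.float64)) for tr in trials]
    F = trials[0].shape[1]
    for tr in trials:
        if tr.shape[1] != F:
            raise ValueError("all trials must share the channel count")
        if tr.shape[0] > target_J:
            raise ValueError(
                f"trial length {tr.shape[0]} exceeds target_J={target_J}"
            )
    n = len(trials)
    values = np.zeros((n, target_J, F))
    mask = np.zeros((n, target_J), dtype=bool)
    for i, tr in enumerate(trials):
        J_i = tr.shape[0]
        values[i, :J_i] = tr
        mask[i, :J_i] = True
    return values, mask


def tukey_outlier_flags(series, quantile_method: str = "linear") -> np.ndarray:
    """Flag values beyond Q3 + 1.5 IQR or below Q1 - 1.5 IQR.

    The quantile convention (default: linear interpolation between order
    statistics, numpy's "linear" / classical type 7) is switchable because
    different conventions move the fences on small samples.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 points for quartiles")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    return (x > q3 + 1.5 * iqr) | (x < q1 - 1.5 * iqr)


def assemble_configuration(facial: np.ndarray | None, bio: np.ndarray | None,
                           config: DatasetConfiguration, labels,
                           pad_mask=None) -> FunctionalTrialSet:
    """Stack the requested channel blocks (facial block first, then bio)
    into a FunctionalTrialSet for one of the five dataset configurations."""
    blocks, names = [], []
    use_facial = config.id != "bio_only"
    use_bio = config.id in ("bio_only", "full_fusion", "selected_facial_plus_bio")
    if use_facial:
        if facial is None:
            raise ValueError(f"{config.id} requires the facial tensor")
        facial = np.asarray(facial, dtype=np.float64)
        if facial.ndim != 3:
            raise ValueError("facial tensor must be n x J x L")
        if config.id.startswith("selected"):
            sel = list(config.selected_indices)
            if max(sel) >= facial.shape[2] or min(sel) < 0:
                raise ValueError("selected landmark index out of range")
            blocks.append(facial[:, :, sel])
            names += [f"landmark{j}" for j in sel]
        else:
            blocks.append(facial)
            names += [f"landmark{j}" for j in range(facial.shape[2])]
    if use_bio:
        if bio is None:
            raise ValueError(f"{config.id} requires the bio tensor")
        bio = np.asarray(bio, dtype=np.float64)
        if bio.ndim != 3 or bio.shape[2] != 2:
            raise ValueError("bio tensor must be n x J x 2")
        blocks.append(bio)
        names += ["ecg", "eda"]
    shapes = {b.shape[:2] for b in blocks}
    if len(shapes) != 1:
        raise ValueError(f"modalities disagree on (n, J): {sorted(shapes)}")
    values = np.concatenate(blocks, axis=2)
    n, J, _ = values.shape
    if pad_mask is not None:
        values = values * np.asarray(pad_mask, dtype=bool)[:, :, None]
    return FunctionalTrialSet(values, make_time_grid(J), labels, pad_mask, names)


# -- raw text readers ------------------------------------------------------


def read_biosignal_file(path, delimiter: str = "\t",
                        rate: float = 300.0) -> BioSignalRecording:
    """Two-column delimited text (ECG, EDA); a non-numeric first row is
    treated as a header."""
    df = pd.read_csv(path, sep=delimiter, header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
    return BioSignalRecording(df.to_numpy(dtype=np.float64), rate=rate)


def read_landmark_file(path, delimiter: str = "\t") -> LandmarkFrameSeries:
    """Long-format delimited text with columns (frame, landmark_id, x, y)."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    required = {"frame", "landmark_id", "x", "y"}
    if not required.issubset(df.columns):
        df = pd.read_csv(path, sep=delimiter, header=None,
                         names=["frame", "landmark_id", "x", "y"])
    frames = np.sort(df["frame"].unique())
    lids = np.sort(df["landmark_id"].unique())
    T, L = frames.size, lids.size
    wide = df.pivot_table(index="frame", columns="landmark_id",
                          values=["x", "y"]).to_numpy()
    coords = np.empty((T, L, 2))
    coords[:, :, 0] = wide[:, :L]
    coords[:, :, 1] = wide[:, L:]
    return LandmarkFrameSeries(coords)
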