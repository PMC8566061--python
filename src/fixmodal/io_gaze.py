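"""Data model and readers/writers for monocular gaze recordings.

A recording is a uniformly sampled (1 kHz) time series of eye position and
target position, both in degrees of visual angle.  Missing eye-position
samples (blinks, removed events) are represented as NaN throughout the
package; target position is never missing.  All sample indexing is 0-based
and half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GazeRecording",
    "FixationTrial",
    "PrecisionSampleSet",
    "GazeFormatError",
    "SamplingError",
    "DEFAULT_DIALECT",
    "read_recording",
    "write_recording",
    "write_results",
    "read_results",
    "segment_trials",
]


class GazeFormatError(ValueError):
    """Input file lacks required columns or has malformed values."""


class SamplingError(ValueError):
    """Timestamps violate the uniform 1 ms sampling contract."""


#: canonical column name -> default on-disk column name
DEFAULT_DIALECT: dict[str, str] = {
    "t": "n",
    "x": "x",
    "y": "y",
    "tx": "xT",
    "ty": "yT",
}

#: columns of the per-fixation results table, in output order
RESULT_COLUMNS = [
    "subject_id",
    "session_id",
    "trial_index",
    "axis",
    "n_samples",
    "log_bf",
    "category",
    "modal_k",
    "classic_precision",
    "max_comp_sd",
    "rms_s2s",
    "mad",
    "components",
]


@dataclass
class GazeRecording:
    """Full-session gaze/target time series sampled at 1 kHz.

    Attributes
    ----------
    t : ndarray
        Sample timestamps in ms, strictly increasing with unit step.
    x, y : ndarray
        Horizontal/vertical gaze position in degrees of visual angle;
        NaN marks missing samples.
    tx, ty : ndarray
        Target position in degrees; never NaN.
    subject_id, session_id : str
        Opaque labels carried through to the results tables.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    subject_id: str = "S000"
    session_id: str = "1"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("x", "y", "tx", "ty"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        for name in ("x", "y", "tx", "ty"):
            if len(getattr(self, name)) != n:
                raise GazeFormatError(
                    f"column {name!r} has length {len(getattr(self, name))}, expected {n}"
                )
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0):
                raise SamplingError(
                    "timestamps are not uniformly spaced at 1 ms; "
                    f"steps range {dt.min()}..{dt.max()}"
                )
        if np.isnan(self.tx).any() or np.isnan(self.ty).any():
            raise GazeFormatError("target position must not contain NaN")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def copy(self) -> "GazeRecording":
        return replace(
            self,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            tx=self.tx.copy(),
            ty=self.ty.copy(),
        )


@dataclass
class FixationTrial:
    """One constant-target epoch and its candidate fixation window.

    ``window`` is a half-open sample range into the recording; ``valid_mask``
    flags, per sample of the window, whether the sample is retained
    (finite in both axes).  A trial is *complete* when its analysis window
    holds exactly 500 valid contiguous samples.
    """

    recording: GazeRecording
    trial_index: int
    target: tuple[float, float]
    window: tuple[int, int]
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        start, stop = self.window
        if stop < start:
            raise ValueError(f"window {self.window} has negative length")
        if self.valid_mask is None:
            self.refresh_valid_mask()
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.valid_mask) != stop - start:
            raise ValueError("valid_mask length must equal window length")

    def refresh_valid_mask(self) -> None:
        """Recompute the mask from the recording's current NaN pattern."""
        start, stop = self.window
        rec = self.recording
        self.valid_mask = np.isfinite(rec.x[start:stop]) & np.isfinite(rec.y[start:stop])

    def __len__(self) -> int:
        return self.window[1] - self.window[0]


@dataclass
class PrecisionSampleSet:
    """500 NaN-free position samples from one axis of one fixation."""

    axis: str
    values: np.ndarray
    subject_id: str = "S000"
    session_id: str = "1"
    trial_index: int = 0

    N_SAMPLES = 500

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"axis must be horizontal/vertical, got {self.axis!r}")
        if len(self.values) != self.N_SAMPLES:
            raise ValueError(
                f"sample set must hold exactly {self.N_SAMPLES} samples, got {len(self.values)}"
            )
        if np.isnan(self.values).any():
            raise ValueError("sample set must be NaN-free")


def read_recording(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sentinel: float | None = None,
    subject_id: str = "S000",
    session_id: str = "1",
) -> GazeRecording:
    """Read a delimited-text gaze recording.

    Parameters
    ----------
    path : path to a CSV/TSV file (delimiter sniffed by pandas).
    dialect : map of canonical names (t, x, y, tx, ty) to file column names.
        Defaults to :data:`DEFAULT_DIALECT`.  The on-disk names are
        configuration because recording exports differ between labs.
    sentinel : optional numeric value encoding missing eye position;
        converted to NaN in x and y.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [col for col in dia.values() if col not in df.columns]
    if missing:
        raise GazeFormatError(f"missing columns {missing} in {path}")
    cols = {canon: df[fname].to_numpy(dtype=float) for canon, fname in dia.items()}
    if sentinel is not None:
        for axis in ("x", "y"):
            cols[axis] = np.where(cols[axis] == sentinel, np.nan, cols[axis])
    return GazeRecording(subject_id=subject_id, session_id=session_id, **cols)


def write_recording(rec: GazeRecording, path: str | Path,
                    dialect: Mapping[str, str] | None = None) -> None:
    """Write a recording in the same dialect :func:`read_recording` accepts."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.DataFrame({dia[c]: getattr(rec, c) for c in ("t", "x", "y", "tx", "ty")})
    df.to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-fixation results table as CSV.

    Infinite log Bayes factors are serialized as the tokens ``inf``/``-inf``
    and restored by :func:`read_results`; full float precision is kept so the
    table round-trips losslessly.
    """
    df = results.copy()
    ordered = [c for c in RESULT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    df[ordered].to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    df = pd.read_csv(path)
    if "session_id" in df.columns:
        df["session_id"] = df["session_id"].astype(str)
    if "subject_id" in df.columns:
        df["subject_id"] = df["subject_id"].astype(str)
    return df


def segment_trials(rec: GazeRecording) -> list[FixationTrial]:
    """Split a recording into constant-target epochs.

    Returns one trial per maximal run of constant (tx, ty), in temporal
    order; the windows partition the recording without overlap.  A recording
    whose target never moves yields a single trial.
    """
    change = np.flatnonzero(np.diff(rec.tx) != 0) + 1
    change_y = np.flatnonzero(np.diff(rec.ty) != 0) + 1
    bounds = np.unique(np.concatenate(([0], change, change_y, [len(rec)])))
    trials = []
    for idx, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        trials.append(
            FixationTrial(
                recording=rec,
                trial_index=idx,
                target=(float(rec.tx[start]), float(rec.ty[start])),
                window=(int(start), int(stop)),
            )
        )
    return trials
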