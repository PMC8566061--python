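"""Fixation cleanup: reduce each target epoch to a clean 500-sample window.

The pipeline applies six steps, in order:

1. remove the average saccade latency by shifting the target signal onto
   the eye signal (the shift minimising total eye-target discrepancy);
2. pick the per-trial analysis window (1-based samples 192-691 of the
   aligned epoch, i.e. 500 samples);
3. remove "blink saccades" — high-velocity artifact ramps flanking a
   blink's NaN gap — using a per-recording fixation velocity-noise
   threshold (FixVelT);
4. remove saccades by radial velocity (peak > 55 deg/s, boundaries at the
   nearest local velocity minima below 30 deg/s);
5. remove residual saccade fragments detected as parabolic arcs in
   sliding 27-sample position windows;
6. remove post-anticipatory-saccade segments where the eye already sits
   near the *next* target.

A trial survives only if its analysis window ends up with exactly 500
contiguous valid samples.  All removals are monotone: NaN only ever grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io_gaze import FixationTrial, GazeRecording, PrecisionSampleSet, segment_trials

__all__ = [
    "PreprocessConfig",
    "VelocityTrace",
    "SaccadeInterval",
    "AlignmentError",
    "ThresholdError",
    "WindowError",
    "compute_velocity",
    "align_signal_to_target",
    "apply_target_shift",
    "select_analysis_window",
    "compute_fix_vel_threshold",
    "remove_blink_saccades",
    "detect_saccades_velocity",
    "remove_parabolic_segments",
    "remove_anticipatory_saccades",
    "filter_complete_fixations",
    "preprocess_recording",
]

log = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """No shift yields any eye/target sample overlap."""


class ThresholdError(ValueError):
    """Too few samples to estimate the fixation velocity threshold."""


class WindowError(ValueError):
    """Trial epoch shorter than the analysis window requires."""


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the cleanup steps (velocities in deg/s).

    ``window_start``/``window_end`` are 1-based inclusive sample numbers
    within the aligned trial epoch, matching the convention in which the
    analysis window runs from sample 192 to sample 691 (500 samples).
    """

    peak_velocity_threshold: float = 55.0
    boundary_velocity_threshold: float = 30.0
    parabolic_window: int = 27
    parabolic_r2: float = 0.6
    parabolic_beta: float = 0.00055  # deg / sample^2
    window_start: int = 192
    window_end: int = 691
    min_valid_samples: int = 500
    fixvelt_cap: float = 55.0
    fixvelt_c: float = 5.0
    fixvelt_min_samples: int = 1000
    as_offset_threshold: float = 2.0  # deg; motivated by the 2 deg minimum target step
    as_approach_fraction: float = 0.5
    align_search_max: int = 500  # samples; covers the 192-316 ms latency range
    smooth_window: int | None = None  # odd Savitzky-Golay window, None = no smoothing
    smooth_order: int = 2


@dataclass
class VelocityTrace:
    """Per-axis and radial velocity in deg/s; NaN where position is NaN."""

    vx: np.ndarray
    vy: np.ndarray
    vr: np.ndarray


@dataclass(frozen=True)
class SaccadeInterval:
    """Half-open sample interval removed by one of the cleanup steps."""

    start: int
    end: int
    kind: str  # saccade | blink_saccade | parabolic_fragment | anticipatory

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval [{self.start}, {self.end}) is empty")


def _smooth_position(p: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smoothing applied per contiguous finite run."""
    from scipy.signal import savgol_filter

    out = p.copy()
    finite = np.isfinite(p)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], finite.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= window:
            out[start:stop] = savgol_filter(p[start:stop], window, order)
    return out


def compute_velocity(rec: GazeRecording, config: PreprocessConfig | None = None) -> VelocityTrace:
    """Central-difference velocity in deg/s at 1 kHz sampling.

    The two-sided stencil makes NaN propagate one sample each side of a
    gap; the first and last samples are NaN.  Optional Savitzky-Golay
    position smoothing (config) is applied before differentiation.
    """
    config = config or PreprocessConfig()
    if len(rec) < 3:
        raise ValueError("recording must hold at least 3 samples for differentiation")
    x, y = rec.x, rec.y
    if config.smooth_window:
        x = _smooth_position(x, config.smooth_window, config.smooth_order)
        y = _smooth_position(y, config.smooth_window, config.smooth_order)
    vx = np.full_like(x, np.nan)
    vy = np.full_like(y, np.nan)
    # (p[i+1] - p[i-1]) / 2 samples * 1000 samples/s
    vx[1:-1] = (x[2:] - x[:-2]) * 500.0
    vy[1:-1] = (y[2:] - y[:-2]) * 500.0
    bad = np.isnan(rec.x) | np.isnan(rec.y)  # stencil skips the centre sample
    vx[bad] = np.nan
    vy[bad] = np.nan
    vr = np.hypot(vx, vy)
    return VelocityTrace(vx=vx, vy=vy, vr=vr)


def align_signal_to_target(
    rec: GazeRecording,
    search_range: tuple[int, int] | None = None,
) -> int:
    """Find the target shift (in samples) best aligning eye and target.

    For each candidate shift ``s`` the target is delayed by ``s`` samples and
    the mean absolute eye-target discrepancy (both axes, NaN excluded) is
    computed; the shift with the lowest discrepancy wins, ties going to the
    smaller shift.  This removes the average saccade latency before the
    per-trial windows are cut.
    """
    cfg_max = PreprocessConfig().align_search_max
    lo, hi = search_range if search_range is not None else (0, cfg_max)
    best_shift, best_cost = None, np.inf
    for s in range(lo, hi + 1):
        if s >= len(rec):
            break
        ex, ey = rec.x[s:], rec.y[s:]
        tx, ty = rec.tx[: len(rec) - s], rec.ty[: len(rec) - s]
        diff = np.abs(ex - tx) + np.abs(ey - ty)
        good = np.isfinite(diff)
        if not good.any():
            continue
        cost = float(np.mean(diff[good]))
        if cost < best_cost:
            best_cost, best_shift = cost, s
    if best_shift is None:
        raise AlignmentError("no shift yields any finite eye/target overlap")
    return best_shift


def apply_target_shift(rec: GazeRecording, shift: int) -> GazeRecording:
    """Delay the target signal by ``shift`` samples (edge-padded).

    After this, target jumps coincide with the eye's response, so epoch
    boundaries from :func:`segment_trials` line up with the eye's fixations.
    """
    out = rec.copy()
    if shift > 0:
        out.tx = np.concatenate((np.full(shift, rec.tx[0]), rec.tx[:-shift]))
        out.ty = np.concatenate((np.full(shift, rec.ty[0]), rec.ty[:-shift]))
    return out


def select_analysis_window(
    trial: FixationTrial, config: PreprocessConfig | None = None
) -> tuple[int, int]:
    """Half-open recording-index bounds of the trial's analysis window.

    The 1-based inclusive sample numbers ``window_start``..``window_end``
    within the epoch convert to the 0-based half-open range
    ``[start + window_start - 1, start + window_end)``.
    """
    config = config or PreprocessConfig()
    start, stop = trial.window
    needed = config.window_end
    if stop - start < needed:
        raise WindowError(
            f"trial epoch has {stop - start} samples; window needs {needed}"
        )
    return start + config.window_start - 1, start + config.window_end


def compute_fix_vel_threshold(
    rec: GazeRecording,
    vel: VelocityTrace,
    config: PreprocessConfig | None = None,
) -> float:
    """Per-recording fixation velocity-noise threshold (FixVelT), deg/s.

    Robust location + spread of the radial velocity over plausible fixation
    samples (below a coarse cap): ``median + c * 1.4826 * MAD``.
    """
    config = config or PreprocessConfig()
    vr = vel.vr
    low = vr[np.isfinite(vr) & (vr < config.fixvelt_cap)]
    if len(low) < config.fixvelt_min_samples:
        raise ThresholdError(
            f"only {len(low)} low-velocity samples; need {config.fixvelt_min_samples}"
        )
    med = float(np.median(low))
    mad = float(np.median(np.abs(low - med)))
    return med + config.fixvelt_c * 1.4826 * mad


def _nan_blocks(rec: GazeRecording) -> list[tuple[int, int]]:
    bad = np.isnan(rec.x) | np.isnan(rec.y)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


def remove_blink_saccades(
    rec: GazeRecording,
    vel: VelocityTrace,
    fixvelt: float,
) -> list[SaccadeInterval]:
    """Mask the high-velocity artifact ramps flanking each NaN gap.

    From the last good sample before a gap, march backward until three
    contiguous samples all fall below FixVelT; the run's sample nearest the
    gap marks the end of the preceding fixation, and everything between it
    (exclusive) and the gap is blink saccade.  Symmetric forward search
    after the gap.  Modifies ``rec`` in place; returns the masked intervals
    (each covers the gap plus any ramps).
    """
    vr = vel.vr
    n = len(rec)
    below = np.isfinite(vr) & (vr < fixvelt)
    intervals: list[SaccadeInterval] = []
    for block_start, block_stop in _nan_blocks(rec):
        # backward: find largest i <= block_start - 1 with below[i-2:i+1] all True
        start = 0
        found = False
        for i in range(block_start - 1, 1, -1):
            if below[i] and below[i - 1] and below[i - 2]:
                start = i + 1  # fixation ends at i; blink saccade starts after
                found = True
                break
        if not found and block_start > 0:
            log.warning("blink-saccade backward search clipped at recording start")
        # forward: find smallest j >= block_stop with below[j:j+3] all True
        end = n
        found = False
        for j in range(block_stop, n - 2):
            if below[j] and below[j + 1] and below[j + 2]:
                end = j  # fixation resumes at j
                found = True
                break
        if not found and block_stop < n:
            log.warning("blink-saccade forward search clipped at recording end")
        rec.x[start:end] = np.nan
        rec.y[start:end] = np.nan
        intervals.append(SaccadeInterval(start, end, "blink_saccade"))
    return _merge(intervals, "blink_saccade")


def _merge(intervals: Sequence[SaccadeInterval], kind: str) -> list[SaccadeInterval]:
    """Merge overlapping/adjacent same-kind intervals into disjoint ones."""
    if not intervals:
        return []
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [SaccadeInterval(a, b, kind) for a, b in merged]


def detect_saccades_velocity(
    rec: GazeRecording,
    vel: VelocityTrace,
    config: PreprocessConfig | None = None,
) -> list[SaccadeInterval]:
    """Velocity-based saccade removal (peak > 55 deg/s).

    Each maximal run of radial velocity above the peak threshold is a
    candidate saccade peak; its boundaries are the nearest samples, on
    either side, that are local minima of radial velocity and below the
    boundary threshold (30 deg/s).  Samples between the boundaries
    (inclusive) are set to NaN in place.  Applying the detector to its own
    output is a fixed point.
    """
    config = config or PreprocessConfig()
    vr = vel.vr
    n = len(rec)
    above = np.isfinite(vr) & (vr > config.peak_velocity_threshold)
    if not above.any():
        return []

    def is_local_min(i: int) -> bool:
        v = vr[i]
        if not np.isfinite(v):
            return False
        left = vr[i - 1] if i > 0 else np.inf
        right = vr[i + 1] if i < n - 1 else np.inf
        # NaN neighbours (gaps) do not disqualify a minimum
        left = np.inf if np.isnan(left) else left
        right = np.inf if np.isnan(right) else right
        return v <= left and v <= right

    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    intervals: list[SaccadeInterval] = []
    for peak_start, peak_stop in zip(edges[::2], edges[1::2]):
        start = 0
        for i in range(int(peak_start) - 1, -1, -1):
            if np.isnan(vr[i]):  # ran into an existing gap
                start = i + 1
                break
            if vr[i] < config.boundary_velocity_threshold and is_local_min(i):
                start = i
                break
        else:
            log.warning("saccade start search clipped at recording start")
        end = n - 1
        for j in range(int(peak_stop), n):
            if np.isnan(vr[j]):
                end = j - 1
                break
            if vr[j] < config.boundary_velocity_threshold and is_local_min(j):
                end = j
                break
        else:
            log.warning("saccade end search clipped at recording end")
        intervals.append(SaccadeInterval(int(start), int(end) + 1, "saccade"))
    intervals = _merge(intervals, "saccade")
    for iv in intervals:
        rec.x[iv.start : iv.end] = np.nan
        rec.y[iv.start : iv.end] = np.nan
    return intervals


def remove_parabolic_segments(
    rec: GazeRecording,
    config: PreprocessConfig | None = None,
) -> list[SaccadeInterval]:
    """Mask residual saccade fragments found as parabolic arcs.

    In every NaN-free 27-sample window (sliding by one sample, each axis
    separately) the position is regressed on the sample index with a
    second-order polynomial.  Windows with R^2 above ``parabolic_r2`` and
    an absolute quadratic coefficient above ``parabolic_beta``
    (deg/sample^2) typically contain small saccades or saccade pieces that
    survived the velocity criterion; all their samples are set to NaN.
    Constant windows (zero variance, R^2 undefined) are never flagged.
    """
    config = config or PreprocessConfig()
    w = config.parabolic_window
    n = len(rec)
    if n < w:
        return []
    idx = np.arange(w, dtype=float)
    design = np.column_stack([idx**2, idx, np.ones(w)])
    pinv = np.linalg.pinv(design)  # (3, w)
    flagged = np.zeros(n, dtype=bool)
    for p in (rec.x, rec.y):
        wins = sliding_window_view(p, w)  # (n - w + 1, w)
        ok = ~np.isnan(wins).any(axis=1)
        if not ok.any():
            continue
        yw = wins[ok]
        coef = yw @ pinv.T  # (m, 3)
        fit = coef @ design.T
        resid = yw - fit
        sst = np.sum((yw - yw.mean(axis=1, keepdims=True)) ** 2, axis=1)
        sse = np.sum(resid**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
        hit = (r2 > config.parabolic_r2) & (np.abs(coef[:, 0]) > config.parabolic_beta)
        starts = np.flatnonzero(ok)[hit]
        for s in starts:
            flagged[s : s + w] = True
    if not flagged.any():
        return []
    rec.x[flagged] = np.nan
    rec.y[flagged] = np.nan
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flagged.view(np.int8), [0]))))
    return [
        SaccadeInterval(int(a), int(b), "parabolic_fragment")
        for a, b in zip(edges[::2], edges[1::2])
    ]


def remove_anticipatory_saccades(
    trial: FixationTrial,
    next_target: tuple[float, float] | None,
    config: PreprocessConfig | None = None,
) -> list[SaccadeInterval]:
    """Mask post-anticipatory-saccade segments within a trial.

    In a perfectly periodic task subjects sometimes saccade to the upcoming
    target before it appears; the saccade itself is removed by the velocity
    steps, but the fixation level that follows sits far from the current
    target.  A contiguous valid segment is marked anticipatory when its
    median offset from the current target exceeds ``as_offset_threshold``
    AND the move brings it at least ``as_approach_fraction`` closer to the
    next target.  The last trial has no next target and is never touched.
    """
    config = config or PreprocessConfig()
    if next_target is None:
        return []
    rec = trial.recording
    start, stop = trial.window
    trial.refresh_valid_mask()
    valid = trial.valid_mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    intervals: list[SaccadeInterval] = []
    tx, ty = trial.target
    nx, ny = next_target
    for a, b in zip(edges[::2], edges[1::2]):
        seg = slice(start + a, start + b)
        off_cur = float(np.median(np.hypot(rec.x[seg] - tx, rec.y[seg] - ty)))
        off_next = float(np.median(np.hypot(rec.x[seg] - nx, rec.y[seg] - ny)))
        if off_cur > config.as_offset_threshold and off_next <= (
            1.0 - config.as_approach_fraction
        ) * off_cur:
            rec.x[seg] = np.nan
            rec.y[seg] = np.nan
            intervals.append(SaccadeInterval(start + int(a), start + int(b), "anticipatory"))
    trial.refresh_valid_mask()
    return intervals


def filter_complete_fixations(
    trials: Sequence[FixationTrial],
    config: PreprocessConfig | None = None,
) -> list[FixationTrial]:
    """Keep trials whose analysis window is one unbroken 500-sample fixation."""
    config = config or PreprocessConfig()
    kept = []
    for trial in trials:
        try:
            wstart, wstop = select_analysis_window(trial, config)
        except WindowError:
            continue
        trial.refresh_valid_mask()
        rel = slice(wstart - trial.window[0], wstop - trial.window[0])
        mask = trial.valid_mask[rel]
        if len(mask) == config.min_valid_samples and mask.all():
            kept.append(trial)
    return kept


def preprocess_recording(
    rec: GazeRecording,
    config: PreprocessConfig | None = None,
) -> tuple[list[PrecisionSampleSet], list[FixationTrial], pd.DataFrame]:
    """Run the full six-step cleanup on one recording.

    Returns the per-axis sample sets of every surviving trial, the surviving
    trials themselves, and a per-step log (samples newly masked and
    intervals found at each step).  The input recording is not modified.
    """
    config = config or PreprocessConfig()
    work = rec.copy()
    steps: list[dict] = []

    def log_step(name: str, before: int, n_intervals: int) -> None:
        after = int(np.isnan(work.x).sum())
        steps.append(
            {"step": name, "intervals": n_intervals, "samples_masked": after - before}
        )

    shift = align_signal_to_target(work, (0, config.align_search_max))
    work = apply_target_shift(work, shift)
    steps.append({"step": "latency_shift", "intervals": 0, "samples_masked": 0})

    nan0 = int(np.isnan(work.x).sum())
    vel = compute_velocity(work, config)
    fixvelt = compute_fix_vel_threshold(work, vel, config)
    blink_ivs = remove_blink_saccades(work, vel, fixvelt)
    log_step("blink_saccades", nan0, len(blink_ivs))

    nan0 = int(np.isnan(work.x).sum())
    vel = compute_velocity(work, config)
    sacc_ivs = detect_saccades_velocity(work, vel, config)
    log_step("velocity_saccades", nan0, len(sacc_ivs))

    nan0 = int(np.isnan(work.x).sum())
    para_ivs = remove_parabolic_segments(work, config)
    log_step("parabolic_fragments", nan0, len(para_ivs))

    trials = segment_trials(work)
    nan0 = int(np.isnan(work.x).sum())
    n_as = 0
    for i, trial in enumerate(trials):
        nxt = trials[i + 1].target if i + 1 < len(trials) else None
        n_as += len(remove_anticipatory_saccades(trial, nxt, config))
    log_step("anticipatory", nan0, n_as)

    kept = filter_complete_fixations(trials, config)
    steps.append(
        {
            "step": "completeness_filter",
            "intervals": len(trials) - len(kept),
            "samples_masked": 0,
        }
    )

    sample_sets: list[PrecisionSampleSet] = []
    for trial in kept:
        wstart, wstop = select_analysis_window(trial, config)
        for axis, sig in (("horizontal", work.x), ("vertical", work.y)):
            sample_sets.append(
                PrecisionSampleSet(
                    axis=axis,
                    values=sig[wstart:wstop].copy(),
                    subject_id=rec.subject_id,
                    session_id=rec.session_id,
                    trial_index=trial.trial_index,
                )
            )
    report = pd.DataFrame(steps)
    report.attrs["latency_shift"] = shift
    report.attrs["fixvelt"] = fixvelt
    report.attrs["recording"] = work  # cleaned copy, for ground-truth comparison
    return sample_sets, kept, report
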