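"""Fluorescence trace processing: dF/F, background subtraction, response
amplitudes, and significance of evoked responses.

The measured somatic fluorescence is corrected for neuropil contamination
by subtracting 0.9x the ring-background trace; pixels in the background
ring that carry transients uncorrelated with the cell are excluded first.
dF/F uses a per-trial baseline with a small additive offset (20 a.u.) in
the denominator to guard against near-zero baselines.  A response is
judged significantly excitatory only if dF/F stays above 3.3x the baseline
SD for at least 0.5 s of consecutive frames, both in a strict majority of
trials and in the trial-averaged trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import (KIND_FM, KIND_TONE, KIND_TWOTONE, DF_GRID, DT_GRID,
                       response_window_frames)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid processing configuration (e.g. degenerate baseline SD)."""


@dataclass
class RoiTraceSet:
    """Trial-aligned dF/F snippets for a set of ROIs.

    ``dff`` has shape (n_roi, n_trials, n_frames); sound onset is at frame
    ``onset_frame`` in every snippet, and frames ``0..onset_frame-1`` are
    the pre-stimulus baseline.
    """

    dff: np.ndarray
    onset_frame: int
    frame_rate: float
    trials: pd.DataFrame        # trial, block, condition_id, onset_time_s
    conditions: pd.DataFrame    # condition metadata (see protocol)
    roi_ids: np.ndarray | None = None

    def __post_init__(self):
        if self.dff.ndim != 3:
            raise ValueError("dff must be (n_roi, n_trials, n_frames)")
        if len(self.trials) != self.dff.shape[1]:
            raise ValueError("trial table does not match dff trial axis")
        if not (0 < self.onset_frame < self.dff.shape[2]):
            raise ValueError("onset_frame must lie inside the snippet")
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.dff.shape[0])

    @property
    def n_roi(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[2]

    def baseline(self) -> np.ndarray:
        """Baseline frames, shape (n_roi, n_trials, onset_frame)."""
        return self.dff[:, :, : self.onset_frame]


# ---------------------------------------------------------------------------
# dF/F and background handling
# ---------------------------------------------------------------------------

def compute_dff(raw: np.ndarray, background: np.ndarray, *,
                coeff: float = 0.9, offset: float = 20.0,
                f0: float | np.ndarray | None = None,
                baseline_slice: slice | None = None) -> np.ndarray:
    """Convert a raw fluorescence trace to dF/F.

    F(t) = raw(t) - coeff * background(t); dF/F = (F - F0) / (F0 + offset).
    F0 defaults to the mean of ``baseline_slice`` of F, or the 10th
    percentile of F when no baseline window is given (session-long traces).

    The small positive ``offset`` (default 20 a.u.) keeps the denominator
    away from zero for dim cells.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs background "
                         f"{background.shape}")
    if offset <= 0:
        raise ConfigError(f"offset must be positive, got {offset}")
    f = raw - coeff * background
    if f0 is None:
        if baseline_slice is not None:
            f0 = f[..., baseline_slice].mean(axis=-1, keepdims=True)
        else:
            f0 = np.percentile(f, 10, axis=-1, keepdims=True)
    return (f - f0) / (np.asarray(f0) + offset)


def exclude_contaminated_pixels(pixel_traces: np.ndarray,
                                cell_trace: np.ndarray, *,
                                event_sd: float = 3.0,
                                corr_threshold: float = 0.2,
                                min_event_frames: int = 2):
    """Flag background-ring pixels contaminated by neighbouring cells.

    A pixel is excluded when it shows large fluorescence events (above
    ``event_sd`` standard deviations of its own trace for at least
    ``min_event_frames`` consecutive frames) while its time course is
    uncorrelated with the cell ROI (Pearson r < ``corr_threshold`` over the
    session).  Returns ``(keep_mask, background_trace)`` where the trace is
    the mean of retained pixels; if every pixel is excluded the unfiltered
    mean is returned with a warning.
    """
    pixel_traces = np.atleast_2d(np.asarray(pixel_traces, dtype=float))
    cell_trace = np.asarray(cell_trace, dtype=float)
    n_pix, n_frames = pixel_traces.shape
    if n_pix < 1:
        raise ValueError("need at least one background pixel")

    keep = np.ones(n_pix, dtype=bool)
    cell_sd = cell_trace.std()
    for p in range(n_pix):
        tr = pixel_traces[p]
        sd = tr.std()
        if sd == 0:
            continue
        z = (tr - tr.mean()) / sd
        events = _max_consecutive(z > event_sd) >= min_event_frames
        if not events:
            continue
        if cell_sd == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(tr, cell_trace)[0, 1])
        if r < corr_threshold:
            keep[p] = False
    if not keep.any():
        logger.warning("all %d background pixels flagged as contaminated; "
                       "falling back to unfiltered mean", n_pix)
        return keep, pixel_traces.mean(axis=0)
    return keep, pixel_traces[keep].mean(axis=0)


def qc_brightness_filter(cell_mean_f: float, background_mean_f: float,
                         min_ratio: float = 1.03) -> bool:
    """Keep only cells at least 3% brighter than their background ring.

    The boundary is inclusive; a relative epsilon absorbs float artifacts
    of the ratio product (1.03 * 100 != 103 exactly).
    """
    if cell_mean_f < 0 or background_mean_f < 0:
        raise ValueError("mean fluorescence must be non-negative")
    return bool(cell_mean_f >= min_ratio * background_mean_f * (1 - 1e-12))


# ---------------------------------------------------------------------------
# response quantification
# ---------------------------------------------------------------------------

def _max_consecutive(mask: np.ndarray) -> np.ndarray:
    """Longest run of True along the last axis."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape[:-1], dtype=int)
    run = np.zeros(mask.shape[:-1], dtype=int)
    for j in range(mask.shape[-1]):
        run = (run + 1) * mask[..., j]
        out = np.maximum(out, run)
    return out


def _window_frames_for_condition(cond_row, frame_rate: float) -> int:
    return response_window_frames(cond_row["kind"], cond_row.get("rate"),
                                  frame_rate)


def response_amplitude(trial_traces: np.ndarray, onset_frame: int,
                       window_frames: int, frame_rate: float):
    """Baseline-subtracted mean dF/F and AUC per trial.

    The baseline is the per-trial mean over pre-onset frames; negative
    amplitudes are preserved here (indices downstream clamp to zero).
    Returns ``(amplitudes, aucs)`` with AUC in dF/F x seconds.
    """
    trial_traces = np.atleast_2d(np.asarray(trial_traces, dtype=float))
    n_frames = trial_traces.shape[-1]
    if onset_frame + window_frames > n_frames:
        raise ValueError(
            f"response window [{onset_frame}, {onset_frame + window_frames}) "
            f"extends past trace end ({n_frames} frames)")
    base = trial_traces[:, :onset_frame].mean(axis=1)
    win = trial_traces[:, onset_frame: onset_frame + window_frames]
    amp = win.mean(axis=1) - base
    auc = amp * (window_frames / frame_rate)
    return amp, auc


def _longest_run_starting_in(mask: np.ndarray, n_start: int) -> np.ndarray:
    """Longest run of True whose first frame lies in the first ``n_start``
    frames of the last axis (runs may extend beyond)."""
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    best = np.zeros(mask.shape[0], dtype=int)
    run = np.zeros(mask.shape[0], dtype=int)
    for j in range(mask.shape[1]):
        run = (run + 1) * mask[:, j]
        started_in_window = (j - run + 1) < n_start
        best = np.maximum(best, np.where(started_in_window, run, 0))
    return best


def detect_significant_response(trial_traces: np.ndarray, onset_frame: int,
                                window_frames: int, frame_rate: float,
                                baseline_sd: float, *,
                                threshold_sd: float = 3.3,
                                min_duration_s: float = 0.5) -> bool:
    """Dual-criterion test for a significant excitatory response.

    dF/F (baseline-subtracted) must exceed ``threshold_sd x baseline_sd``
    for at least ``min_duration_s`` of consecutive frames, (1) in strictly
    more than half of the trials and (2) in the trial-averaged trace.  A
    qualifying run must begin inside the response window but may extend
    beyond it: the slow indicator stretches responses past short windows
    (the fastest sweep window is 0.35 s, less than the 0.5-s run
    requirement).
    """
    trial_traces = np.atleast_2d(np.asarray(trial_traces, dtype=float))
    if trial_traces.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    if baseline_sd <= 0:
        raise ConfigError("baseline SD must be positive; set min_baseline_sd "
                          "to supply an absolute floor")
    thr = threshold_sd * baseline_sd
    min_frames = int(np.ceil(min_duration_s * frame_rate))

    base = trial_traces[:, :onset_frame].mean(axis=1, keepdims=True)
    sub = trial_traces - base
    # window + min_frames frames decide whether any run starting inside
    # the window reaches min_frames
    stop = onset_frame + window_frames + min_frames
    post = sub[:, onset_frame:stop]
    per_trial = _longest_run_starting_in(post > thr,
                                         window_frames) >= min_frames
    crit1 = per_trial.sum() * 2 > trial_traces.shape[0]

    mean_post = sub.mean(axis=0)[onset_frame:stop]
    crit2 = _longest_run_starting_in(mean_post[None, :] > thr,
                                     window_frames)[0] >= min_frames
    return bool(crit1 and crit2)


# ---------------------------------------------------------------------------
# response table
# ---------------------------------------------------------------------------

@dataclass
class ResponseTable:
    """Per-(ROI, condition, trial) amplitudes plus significance flags.

    ``trials`` columns: roi, condition_id, trial, amplitude, auc.
    ``significance``: boolean array (n_roi, n_conditions) indexed by
    position in ``conditions``.
    """

    trials: pd.DataFrame
    significance: np.ndarray
    conditions: pd.DataFrame
    frame_rate: float
    roi_ids: np.ndarray
    baseline_sd: np.ndarray  # per ROI

    _amp_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    def _roi_index(self, roi) -> int:
        idx = np.nonzero(self.roi_ids == roi)[0]
        if len(idx) != 1:
            raise KeyError(f"unknown roi {roi!r}")
        return int(idx[0])

    def trial_amplitudes(self, roi, condition_id: int) -> np.ndarray:
        key = "trial_amps"
        if key not in self._amp_cache:
            piv = self.trials.pivot_table(index=["roi", "condition_id"],
                                          values="amplitude",
                                          aggfunc=list)
            self._amp_cache[key] = {k: np.asarray(v)
                                    for k, v in piv["amplitude"].items()}
        return self._amp_cache[key][(roi, condition_id)]

    def mean_amplitude(self, roi, condition_id: int) -> float:
        return float(self.trial_amplitudes(roi, condition_id).mean())

    def is_significant(self, roi, condition_id: int) -> bool:
        return bool(self.significance[self._roi_index(roi), condition_id])

    # ---- convenience accessors used by the analysis modules ----

    def _grid(self) -> np.ndarray:
        """9x9 array of two-tone condition ids indexed [dF, dT]."""
        if "grid" not in self._amp_cache:
            grid = np.full((len(DF_GRID), len(DT_GRID)), -1, dtype=int)
            tt = self.conditions[self.conditions["kind"] == KIND_TWOTONE]
            for _, row in tt.iterrows():
                i = int(np.argmin(np.abs(DF_GRID - row["dF"])))
                j = int(np.argmin(np.abs(DT_GRID - row["dT"])))
                grid[i, j] = int(row["condition_id"])
            self._amp_cache["grid"] = grid
        return self._amp_cache["grid"]

    def twotone_mean_matrix(self, roi) -> np.ndarray:
        """9x9 matrix of trial-mean two-tone amplitudes, indexed [dF, dT]."""
        grid = self._grid()
        out = np.empty(grid.shape)
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                out[i, j] = self.mean_amplitude(roi, grid[i, j])
        return out

    def twotone_sig_matrix(self, roi) -> np.ndarray:
        grid = self._grid()
        r = self._roi_index(roi)
        return self.significance[r][grid]

    def tone_condition_ids(self):
        """(center_id, array of 9 dF-tone ids ordered by DF_GRID)."""
        tones = self.conditions[self.conditions["kind"] == KIND_TONE]
        center = int(tones[tones["role"] == "center"]["condition_id"].iloc[0])
        df_tones = tones[tones["role"] == "df"].sort_values("dF")
        return center, df_tones["condition_id"].to_numpy(dtype=int)

    def fm_condition_ids(self):
        """dict (rate, direction) -> condition_id."""
        fm = self.conditions[self.conditions["kind"] == KIND_FM]
        return {(float(r), d): int(c) for r, d, c in
                zip(fm["rate"], fm["direction"], fm["condition_id"])}


def process_dataset(ts: RoiTraceSet, *, threshold_sd: float = 3.3,
                    min_duration_s: float = 0.5,
                    min_baseline_sd: float | None = None) -> ResponseTable:
    """Quantify every (ROI, condition): trial amplitudes, AUC, significance.

    The baseline SD used for the excitation threshold is estimated per ROI
    from the pooled baseline-subtracted pre-onset frames of all trials.
    ``min_baseline_sd`` supplies an absolute floor for noise-free synthetic
    data, where the SD would otherwise degenerate to zero.
    """
    n_roi, n_trials, _ = ts.dff.shape
    frame_rate = ts.frame_rate
    onset = ts.onset_frame

    base = ts.baseline()
    base_sub = base - base.mean(axis=2, keepdims=True)
    baseline_sd = base_sub.reshape(n_roi, -1).std(axis=1)
    if min_baseline_sd is not None:
        baseline_sd = np.maximum(baseline_sd, min_baseline_sd)
    if np.any(baseline_sd <= 0):
        raise ConfigError("zero baseline SD for some ROI; set min_baseline_sd")

    cond_ids = ts.conditions["condition_id"].to_numpy(dtype=int)
    window = {int(row["condition_id"]):
              _window_frames_for_condition(row, frame_rate)
              for _, row in ts.conditions.iterrows()}

    trial_cond = ts.trials["condition_id"].to_numpy(dtype=int)
    rows_roi, rows_cond, rows_trial, rows_amp, rows_auc = [], [], [], [], []
    significance = np.zeros((n_roi, cond_ids.max() + 1), dtype=bool)

    for cid in cond_ids:
        t_idx = np.nonzero(trial_cond == cid)[0]
        w = window[cid]
        for r in range(n_roi):
            tr = ts.dff[r, t_idx]
            amp, auc = response_amplitude(tr, onset, w, frame_rate)
            rows_roi.extend([ts.roi_ids[r]] * len(t_idx))
            rows_cond.extend([cid] * len(t_idx))
            rows_trial.extend(t_idx.tolist())
            rows_amp.extend(amp.tolist())
            rows_auc.extend(auc.tolist())
            significance[r, cid] = detect_significant_response(
                tr, onset, w, frame_rate, baseline_sd[r],
                threshold_sd=threshold_sd, min_duration_s=min_duration_s)

    trials = pd.DataFrame({"roi": rows_roi, "condition_id": rows_cond,
                           "trial": rows_trial, "amplitude": rows_amp,
                           "auc": rows_auc})
    return ResponseTable(trials=trials, significance=significance,
                         conditions=ts.conditions, frame_rate=frame_rate,
                         roi_ids=np.asarray(ts.roi_ids),
                         baseline_sd=baseline_sd)
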