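"""Stimulus protocol: the two-tone dF-dT grid, single tones, and FM sweeps.

The two-tone design crosses nine frequency offsets (dF: -1 to +1 octave
around the center tone, 0.25-octave steps) with nine onset-to-onset
intervals (dT: -100 to +100 ms, 25-ms steps; negative dT means the dF tone
leads).  Component tones are presented alone as well, so linearity of
summation can be computed.  FM sweeps span 4 octaves at six rates
(2.5-80 oct/s) in both directions.  Stimuli are delivered in randomized
blocks: each block contains every condition exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: frequency offsets of the dF tone relative to the center tone (octaves)
DF_GRID = np.round(np.linspace(-1.0, 1.0, 9), 4)
#: onset-to-onset intervals (ms); negative values = dF tone leads
DT_GRID = np.linspace(-100.0, 100.0, 9)
#: absolute FM sweep rates (oct/s)
FM_RATES = (2.5, 5.0, 10.0, 20.0, 40.0, 80.0)
#: octave span of the FM sweeps (4-64 kHz)
FM_SPAN_OCT = 4.0
#: sweep directions
FM_DIRECTIONS = ("up", "down")

# condition kinds
KIND_TWOTONE = "twotone"
KIND_TONE = "tone"
KIND_FM = "fm"
KIND_PURETONE = "puretone"  # 1-s pure tones (best-frequency mapping)


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Condition table plus the randomized trial schedule.

    Attributes
    ----------
    conditions : pandas.DataFrame
        One row per distinct stimulus, columns ``condition_id``, ``kind``,
        ``dF``, ``dT``, ``rate``, ``direction``, ``role`` (``center`` /
        ``df`` for single tones).
    trials : pandas.DataFrame
        One row per presentation, columns ``trial``, ``block``,
        ``condition_id``, ``onset_time_s``.
    """

    conditions: pd.DataFrame
    trials: pd.DataFrame
    n_trials_per_condition: int
    frame_rate: float
    iti_s: float
    n_baseline_frames: int
    n_post_frames: int

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_frames(self) -> int:
        """Frames per aligned trial snippet (baseline + post-onset)."""
        return self.n_baseline_frames + self.n_post_frames

    @property
    def onset_frame(self) -> int:
        """Frame index of sound onset within each snippet."""
        return self.n_baseline_frames

    def condition_id(self, kind: str, **sel) -> int:
        """Look up a single condition id by kind and metadata fields."""
        df = self.conditions[self.conditions["kind"] == kind]
        for key, val in sel.items():
            col = df[key]
            if pd.api.types.is_float_dtype(col):
                df = df[np.isclose(col, val)]
            else:
                df = df[col == val]
        if len(df) != 1:
            raise KeyError(f"condition lookup ({kind}, {sel}) matched {len(df)} rows")
        return int(df["condition_id"].iloc[0])

    def twotone_condition_grid(self) -> np.ndarray:
        """9x9 array of condition ids indexed [dF, dT]."""
        grid = np.full((len(DF_GRID), len(DT_GRID)), -1, dtype=int)
        tt = self.conditions[self.conditions["kind"] == KIND_TWOTONE]
        for _, row in tt.iterrows():
            i = int(np.argmin(np.abs(DF_GRID - row["dF"])))
            j = int(np.argmin(np.abs(DT_GRID - row["dT"])))
            grid[i, j] = int(row["condition_id"])
        return grid


def response_window_frames(kind: str, rate: float | None, frame_rate: float,
                           fm_rate: float | None = None) -> int:
    """Length (frames) of the response-detection window for a condition kind.

    Two-tone stimuli and their 20-ms component tones use 1 s from sound
    onset; 1-s pure tones use 1.2 s; FM sweeps use sound onset to 0.3 s
    after sound offset (sweep duration = 4 oct / rate).
    """
    if kind in (KIND_TWOTONE, KIND_TONE):
        dur = 1.0
    elif kind == KIND_PURETONE:
        dur = 1.2
    elif kind == KIND_FM:
        r = fm_rate if fm_rate is not None else rate
        if r is None or r <= 0:
            raise ProtocolError("FM condition requires a positive sweep rate")
        dur = FM_SPAN_OCT / r + 0.3
    else:
        raise ProtocolError(f"unknown condition kind {kind!r}")
    # epsilon guards float artifacts, e.g. 1.9000000000000001 * 30
    return int(np.ceil(dur * frame_rate - 1e-9))


def build_condition_table(include_fm: bool = True) -> pd.DataFrame:
    """Enumerate the distinct stimulus conditions of the two-tone protocol."""
    rows = []
    cid = 0
    for dF in DF_GRID:
        for dT in DT_GRID:
            rows.append(dict(condition_id=cid, kind=KIND_TWOTONE, dF=dF, dT=dT,
                             rate=np.nan, direction="", role=""))
            cid += 1
    rows.append(dict(condition_id=cid, kind=KIND_TONE, dF=np.nan, dT=np.nan,
                     rate=np.nan, direction="", role="center"))
    cid += 1
    for dF in DF_GRID:
        rows.append(dict(condition_id=cid, kind=KIND_TONE, dF=dF, dT=np.nan,
                         rate=np.nan, direction="", role="df"))
        cid += 1
    if include_fm:
        for rate in FM_RATES:
            for direction in FM_DIRECTIONS:
                rows.append(dict(condition_id=cid, kind=KIND_FM, dF=np.nan,
                                 dT=np.nan, rate=rate, direction=direction,
                                 role=""))
                cid += 1
    return pd.DataFrame(rows)


def build_protocol(n_trials: int = 5, iti_s: float = 5.0,
                   frame_rate: float = 30.0, include_fm: bool = True,
                   seed: int = 0, n_baseline_frames: int = 30,
                   post_s: float = 2.5) -> StimulusProtocol:
    """Build the full stimulus schedule.

    Parameters
    ----------
    n_trials : int
        Repeats per condition; each repeat lives in its own randomized
        block containing every condition exactly once.
    iti_s : float
        Inter-trial interval (s).
    frame_rate : float
        Imaging frame rate (Hz).
    include_fm : bool
        Whether to include the 12 FM sweep conditions (6 rates x 2
        directions).
    seed : int
        Seed for the block randomization.
    n_baseline_frames : int
        Pre-onset frames kept in each aligned trial snippet.
    post_s : float
        Post-onset duration of each snippet (s); must cover the longest
        response window (1.9 s for the 2.5 oct/s sweep).
    """
    if n_trials <= 0:
        raise ProtocolError(f"n_trials must be positive, got {n_trials}")
    if frame_rate <= 0:
        raise ProtocolError(f"frame_rate must be positive, got {frame_rate}")
    if iti_s <= 0:
        raise ProtocolError(f"iti_s must be positive, got {iti_s}")

    conditions = build_condition_table(include_fm=include_fm)
    n_post = int(np.ceil(post_s * frame_rate))
    longest = max(
        response_window_frames(k, r, frame_rate)
        for k, r in zip(conditions["kind"], conditions["rate"])
    )
    if n_post < longest:
        raise ProtocolError(
            f"post_s={post_s} covers {n_post} frames but the longest "
            f"response window needs {longest}")

    rng = np.random.default_rng(seed)
    n_cond = len(conditions)
    order = np.concatenate([rng.permutation(n_cond) for _ in range(n_trials)])
    blocks = np.repeat(np.arange(n_trials), n_cond)
    trials = pd.DataFrame({
        "trial": np.arange(n_trials * n_cond),
        "block": blocks,
        "condition_id": order,
        "onset_time_s": np.arange(n_trials * n_cond) * iti_s,
    })
    return StimulusProtocol(conditions=conditions, trials=trials,
                            n_trials_per_condition=n_trials,
                            frame_rate=frame_rate, iti_s=iti_s,
                            n_baseline_frames=n_baseline_frames,
                            n_post_frames=n_post)
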