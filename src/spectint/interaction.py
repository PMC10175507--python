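"""Spectrotemporal interaction maps from two-tone responses.

For each neuron and each (dF, dT) pair the linearity index

    LI = (T - L) / (T + L)

compares the two-tone response T against the linear sum L of the two
component-tone responses (amplitudes clamped at zero first, so LI stays in
[-1, 1]).  LI > 0 is supralinear (facilitative) integration, LI < 0
sublinear (suppressive).  The 9x9 LI grid over dF (octaves) and dT (ms) is
a neuron's spectrotemporal interaction map.  This module builds, smooths
and aggregates these maps, tests each grid cell for significant
nonlinearity by trial resampling, classifies neurons by two-tone timing
preference, and computes the temporal asymmetry index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocol import DF_GRID, DT_GRID
from .traces import ResponseTable

#: grid spacing (octaves, ms) used to express the smoothing SD in stimulus units
DF_SPACING_OCT = 0.25
DT_SPACING_MS = 25.0

#: default dF subset used for timing-preference averaging
CLASSIFY_DF_SET = (-1.0, -0.5, 0.0, 0.5, 1.0)

FACILITATIVE = "facilitative"
SUPPRESSIVE = "suppressive"
NONE = "none"

TIMING_LABELS = ("coincident_preferring", "negative_dT_preferring",
                 "positive_dT_preferring", "symmetric_shift_preferring",
                 "unclassified")


@dataclass
class InteractionMap:
    """Per-neuron 9x9 linearity-index grid (rows dF -1..+1 oct, cols dT
    -100..+100 ms) with validity mask, smoothed map and per-cell
    facilitation/suppression significance flags.  Invalid cells hold NaN.
    """

    li: np.ndarray
    valid: np.ndarray
    li_smoothed: np.ndarray
    fac_sig: np.ndarray
    supp_sig: np.ndarray
    roi: object = None

    def __post_init__(self):
        if np.any(self.fac_sig & self.supp_sig):
            raise ValueError("a grid cell cannot be both facilitative and "
                             "suppressive")


@dataclass
class TimingPreference:
    label: str
    coincident_amp: float
    shifted_amp: float
    pos_amp: float
    neg_amp: float


def compute_linearity_index(t: float, l: float) -> float:
    """LI = (T - L)/(T + L) after clamping both amplitudes at zero.

    Returns NaN when both clamped amplitudes are zero (LI undefined).
    """
    t = max(float(t), 0.0)
    l = max(float(l), 0.0)
    if t + l == 0.0:
        return np.nan
    return (t - l) / (t + l)


def test_nonlinearity(twotone_amps, center_amps, df_amps,
                      alpha: float = 0.1) -> str:
    """Classify one dF-dT pair as facilitative, suppressive or neither.

    The null distribution is every pairwise sum of single-trial component
    amplitudes (n_center x n_df values, e.g. 5 x 5 = 25).  Two-tone trial
    amplitudes are compared against it with a two-sided Wilcoxon rank-sum
    test; the direction is the sign of (mean two-tone - mean null).  The
    relatively permissive default alpha of 0.1 reflects the small number
    of trials.
    """
    tt = np.asarray(twotone_amps, dtype=float)
    c = np.asarray(center_amps, dtype=float)
    d = np.asarray(df_amps, dtype=float)
    if len(tt) < 2 or len(c) < 2 or len(d) < 2:
        raise ValueError("need at least 2 trials per condition")
    null = np.add.outer(c, d).ravel()
    pooled = np.concatenate([tt, null])
    if np.ptp(pooled) == 0:
        return NONE
    res = stats.mannwhitneyu(tt, null, alternative="two-sided",
                             method="auto")
    if res.pvalue >= alpha:
        return NONE
    return FACILITATIVE if tt.mean() > null.mean() else SUPPRESSIVE


def smooth_map(li: np.ndarray, valid: np.ndarray,
               sigma_grid: float = 0.4, truncate: float = 4.0) -> np.ndarray:
    """Mask-aware 2-D Gaussian smoothing of an LI grid.

    The kernel (SD ``sigma_grid`` in grid units; 0.4 corresponds to
    0.1 oct and 10 ms at the 0.25-oct / 25-ms grid spacing) is renormalized
    over the valid cells inside its support, so invalid cells and edges do
    not drag estimates toward zero.  Output is NaN where no valid cell lies
    within ``truncate`` SDs.
    """
    if sigma_grid <= 0:
        raise ValueError("sigma_grid must be positive")
    li = np.asarray(li, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n_i, n_j = li.shape
    radius = int(np.ceil(truncate * sigma_grid))
    out = np.full_like(li, np.nan)
    vi, vj = np.nonzero(valid)
    if len(vi) == 0:
        return out
    for i in range(n_i):
        for j in range(n_j):
            d2 = (vi - i) ** 2 + (vj - j) ** 2
            close = d2 <= radius ** 2
            if not close.any():
                continue
            w = np.exp(-d2[close] / (2.0 * sigma_grid ** 2))
            out[i, j] = np.sum(w * li[vi[close], vj[close]]) / np.sum(w)
    return out


def build_interaction_map(rt: ResponseTable, roi, *, alpha: float = 0.1,
                          sigma_grid: float = 0.4,
                          run_significance: bool = True) -> InteractionMap:
    """Build a neuron's spectrotemporal interaction map.

    A grid cell gets an LI only if a significant excitatory response was
    evoked by the dF-dT pair itself, the center tone, or the dF tone
    (otherwise neither T nor L is measurable above noise and the cell is
    marked invalid).  T is the clamped trial-mean two-tone amplitude; L is
    the sum of the clamped trial-mean center- and dF-tone amplitudes.
    """
    center_id, df_ids = rt.tone_condition_ids()
    if len(df_ids) != len(DF_GRID):
        raise ValueError("missing single-tone conditions")
    grid = rt._grid()
    n_df, n_dt = grid.shape

    center_tr = rt.trial_amplitudes(roi, center_id)
    center_amp = max(center_tr.mean(), 0.0)
    center_sig = rt.is_significant(roi, center_id)

    li = np.full((n_df, n_dt), np.nan)
    valid = np.zeros((n_df, n_dt), dtype=bool)
    fac = np.zeros((n_df, n_dt), dtype=bool)
    supp = np.zeros((n_df, n_dt), dtype=bool)
    tt_sig = rt.twotone_sig_matrix(roi)

    for i in range(n_df):
        df_tr = rt.trial_amplitudes(roi, int(df_ids[i]))
        df_amp = max(df_tr.mean(), 0.0)
        df_sig = rt.is_significant(roi, int(df_ids[i]))
        l = center_amp + df_amp
        for j in range(n_dt):
            if not (tt_sig[i, j] or center_sig or df_sig):
                continue
            tt_tr = rt.trial_amplitudes(roi, int(grid[i, j]))
            val = compute_linearity_index(tt_tr.mean(), l)
            if np.isnan(val):
                continue
            li[i, j] = val
            valid[i, j] = True
            if run_significance:
                verdict = test_nonlinearity(tt_tr, center_tr, df_tr,
                                            alpha=alpha)
                fac[i, j] = verdict == FACILITATIVE
                supp[i, j] = verdict == SUPPRESSIVE

    smoothed = smooth_map(li, valid, sigma_grid=sigma_grid)
    return InteractionMap(li=li, valid=valid, li_smoothed=smoothed,
                          fac_sig=fac, supp_sig=supp, roi=roi)


def aggregate_population_map(maps, use_smoothed: bool = True):
    """Cell-wise mean LI across neurons, with the per-cell neuron count.

    Invalid cells are excluded from the mean; returns ``(mean, n)``.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    stack = np.stack([m.li_smoothed if use_smoothed else m.li for m in maps])
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(stack, axis=0) /
                        np.maximum(n, 1), np.nan)
    return mean, n


def normalized_magnitude_profile(rt: ResponseTable, rois) -> np.ndarray:
    """Mean normalized two-tone amplitude per dT across ROI-dF pairs.

    Only ROI-dF pairs with a significant excitatory response at >= 1 dT
    contribute; each pair's 9 dT amplitudes (clamped at zero) are divided
    by their maximum before averaging.  Pairs whose maximum is <= 0 are
    excluded.
    """
    profiles = []
    for roi in rois:
        amps = np.clip(rt.twotone_mean_matrix(roi), 0.0, None)
        sig = rt.twotone_sig_matrix(roi)
        for i in range(amps.shape[0]):
            if not sig[i].any():
                continue
            m = amps[i].max()
            if m <= 0:
                continue
            profiles.append(amps[i] / m)
    if not profiles:
        raise ValueError("no qualifying ROI-dF pairs")
    return np.mean(profiles, axis=0)


def classify_timing_preference(rt: ResponseTable, roi, *,
                               ratio: float = 1.5,
                               df_set=CLASSIFY_DF_SET) -> TimingPreference:
    """Classify a two-tone-responsive neuron by its timing preference.

    Coincident amplitude is averaged over ``df_set`` at dT = 0; shifted
    amplitude over the same dFs x 8 shifted dTs (40 pairs for a 5-dF set).
    A neuron is coincidence-preferring when the coincident amplitude is
    more than ``ratio`` (default 1.5) times the shifted one, and vice
    versa; shift-preferring neurons are subdivided into negative- /
    positive-dT-preferring by the same ratio rule, else symmetric.
    """
    return classify_from_matrix(rt.twotone_mean_matrix(roi), ratio=ratio,
                                df_set=df_set)


def classify_from_matrix(amp_matrix: np.ndarray, *, ratio: float = 1.5,
                         df_set=CLASSIFY_DF_SET) -> TimingPreference:
    """Timing-preference rule applied to a 9x9 amplitude matrix."""
    amps = np.clip(np.asarray(amp_matrix, dtype=float), 0.0, None)
    df_mask = np.isin(np.round(DF_GRID, 4), np.round(df_set, 4))
    dt0 = np.isclose(DT_GRID, 0.0)

    coincident = amps[np.ix_(df_mask, dt0)].mean()
    shifted = amps[np.ix_(df_mask, ~dt0)].mean()
    neg = amps[np.ix_(df_mask, DT_GRID < 0)].mean()
    pos = amps[np.ix_(df_mask, DT_GRID > 0)].mean()

    if coincident > ratio * shifted:
        label = "coincident_preferring"
    elif shifted > ratio * coincident:
        if neg > ratio * pos:
            label = "negative_dT_preferring"
        elif pos > ratio * neg:
            label = "positive_dT_preferring"
        else:
            label = "symmetric_shift_preferring"
    else:
        label = "unclassified"
    return TimingPreference(label=label, coincident_amp=float(coincident),
                            shifted_amp=float(shifted), pos_amp=float(pos),
                            neg_amp=float(neg))


def asymmetry_index(rt: ResponseTable, roi) -> float:
    """Temporal asymmetry |(P - N)/(P + N)| of two-tone responses.

    P and N are the summed (clamped) response amplitudes over all two-tone
    pairs with positive and negative dT respectively.  NaN when P + N = 0.
    """
    return asymmetry_from_matrix(rt.twotone_mean_matrix(roi))


def asymmetry_from_matrix(amp_matrix: np.ndarray) -> float:
    """Asymmetry index |(P - N)/(P + N)| from a 9x9 amplitude matrix."""
    amps = np.clip(np.asarray(amp_matrix, dtype=float), 0.0, None)
    p = amps[:, DT_GRID > 0].sum()
    n = amps[:, DT_GRID < 0].sum()
    if p + n == 0:
        return np.nan
    return abs((p - n) / (p + n))


def map_two_tone_to_fm_rate(dF: float, dT: float) -> float:
    """Equivalent FM rate (oct/s) of a two-tone (dF, dT) pair.

    A 0.25-oct step over 100 ms corresponds to 2.5 oct/s; 1 oct over
    25 ms to 40 oct/s.  Undefined for coincident pairs (dT = 0).
    """
    if dT == 0:
        raise ValueError("FM rate undefined for coincident tones (dT = 0)")
    return abs(dF) / (abs(dT) / 1000.0)
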