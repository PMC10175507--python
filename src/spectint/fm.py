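"""FM-sweep direction selectivity and its link to interaction-map asymmetry.

The direction selectivity index DSI = (U - D)/(U + D) compares responses
to upward (U) and downward (D) frequency sweeps (amplitudes clamped at
zero).  An interaction map predicts sweep preference through its quadrant
structure: supralinearity in the dF>0,dT>0 and dF<0,dT<0 quadrants (the
"Upward region") predicts upward selectivity, the complementary quadrants
("Downward region") downward selectivity, and sublinearity predicts the
opposite.  Bias_fac and Bias_supp summarize that asymmetry as the
difference of summed positive / negative LI between the two regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocol import DF_GRID, DT_GRID
from .traces import ResponseTable

#: FM rates (oct/s) pooled for the single-value DSI; cortical inhibition is
#: predicted to shape direction selectivity in this middle-speed range
DSI_SUMMARY_RATES = (10.0, 20.0, 40.0)


@dataclass
class SweepTuning:
    """Per-neuron FM amplitudes and direction selectivity.

    ``amp``/``sig`` map (rate, direction) to trial-mean amplitude /
    significance; ``dsi_per_rate`` holds a DSI for each responsive rate
    (significant in >= 1 direction), NaN elsewhere; ``dsi_mid`` is the
    single DSI from amplitudes averaged over the summary rates.
    """

    roi: object
    amp: dict
    sig: dict
    dsi_per_rate: dict
    dsi_mid: float
    responsive_rates: tuple


@dataclass
class BiasScores:
    bias_fac: float
    bias_supp: float


def compute_dsi(u: float, d: float) -> float:
    """DSI = (U - D)/(U + D) with amplitudes clamped at zero.

    NaN when both clamped amplitudes are zero.
    """
    u = max(float(u), 0.0)
    d = max(float(d), 0.0)
    if u + d == 0.0:
        return np.nan
    return (u - d) / (u + d)


def sweep_tuning(rt: ResponseTable, roi, *,
                 summary_rates=DSI_SUMMARY_RATES) -> SweepTuning:
    """Extract a neuron's FM tuning from the response table."""
    fm_ids = rt.fm_condition_ids()
    if not fm_ids:
        raise ValueError("response table has no FM conditions")
    amp, sig = {}, {}
    for key, cid in fm_ids.items():
        amp[key] = rt.mean_amplitude(roi, cid)
        sig[key] = rt.is_significant(roi, cid)
    rates = sorted({r for r, _ in fm_ids})
    responsive = tuple(r for r in rates
                       if sig.get((r, "up")) or sig.get((r, "down")))
    dsi_per_rate = {r: (compute_dsi(amp[(r, "up")], amp[(r, "down")])
                        if r in responsive else np.nan)
                    for r in rates}
    dsi_mid = dsi_summary(amp, sig, rates=summary_rates)
    return SweepTuning(roi=roi, amp=amp, sig=sig, dsi_per_rate=dsi_per_rate,
                       dsi_mid=dsi_mid, responsive_rates=responsive)


def dsi_summary(amp: dict, sig: dict, rates=DSI_SUMMARY_RATES) -> float:
    """Single DSI from amplitudes averaged across the given rates.

    U and D are averaged over the qualifying rates (those with a
    significant response in at least one direction) *before* the DSI is
    computed; this is not the mean of per-rate DSIs.  NaN when no rate
    qualifies.
    """
    qual = [r for r in rates if sig.get((r, "up")) or sig.get((r, "down"))]
    if not qual:
        return np.nan
    u = np.mean([max(amp[(r, "up")], 0.0) for r in qual])
    d = np.mean([max(amp[(r, "down")], 0.0) for r in qual])
    return compute_dsi(u, d)


def responsive_fraction_by_rate(rt: ResponseTable, rois) -> dict:
    """Fraction of ROIs with a significant response at each |rate|.

    A neuron counts as responsive at a rate if either sweep direction
    evoked a significant excitatory response (FM window: sound onset to
    0.3 s after offset).
    """
    rois = list(rois)
    if not rois:
        raise ValueError("empty ROI set")
    fm_ids = rt.fm_condition_ids()
    rates = sorted({r for r, _ in fm_ids})
    out = {}
    for r in rates:
        n = sum(1 for roi in rois
                if rt.is_significant(roi, fm_ids[(r, "up")])
                or rt.is_significant(roi, fm_ids[(r, "down")]))
        out[r] = n / len(rois)
    return out


def _quadrant_masks():
    df = DF_GRID[:, None]
    dt = DT_GRID[None, :]
    upward = ((df > 0) & (dt > 0)) | ((df < 0) & (dt < 0))
    downward = ((df > 0) & (dt < 0)) | ((df < 0) & (dt > 0))
    return upward, downward


def linearity_bias(li: np.ndarray, valid: np.ndarray | None = None) -> BiasScores:
    """Bias_fac and Bias_supp of an interaction map.

    Bias_fac = sum of positive LI in the Upward region minus the Downward
    region; Bias_supp likewise for negative LI.  The dF = 0 row and dT = 0
    column are excluded (strict quadrants); sums run over valid cells of
    the raw (unsmoothed) map.  Both NaN when no valid off-axis cell exists.
    """
    li = np.asarray(li, dtype=float)
    if valid is None:
        valid = ~np.isnan(li)
    up, down = _quadrant_masks()
    ok = valid & ~np.isnan(li)
    if not (ok & (up | down)).any():
        return BiasScores(bias_fac=np.nan, bias_supp=np.nan)

    def region_sum(region, positive):
        vals = li[ok & region]
        vals = vals[vals > 0] if positive else vals[vals < 0]
        return vals.sum()

    bias_fac = region_sum(up, True) - region_sum(down, True)
    bias_supp = region_sum(up, False) - region_sum(down, False)
    return BiasScores(bias_fac=float(bias_fac), bias_supp=float(bias_supp))


def correlate_dsi_bias(dsi_values, bias_values):
    """Pearson correlation between DSI and a linearity-index bias.

    Non-finite pairs are dropped; the p value is the two-sided t-test on R
    with n - 2 degrees of freedom.  Returns ``(r, p, n)``; (NaN, NaN, n)
    when fewer than 3 pairs remain or either variable is constant.
    """
    x = np.asarray(dsi_values, dtype=float)
    y = np.asarray(bias_values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, n
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n
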