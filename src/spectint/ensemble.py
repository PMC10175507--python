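"""Population response vectors and ensemble-level two-tone integration.

For each stimulus condition a population response vector concatenates the
trial-mean amplitudes of all ROIs (pooled across animals); entries whose
response was not significant are forced to zero for de-noising.  Two-tone
ensemble patterns are then compared, via Pearson correlation in this
high-dimensional activity space, against the linear sum of the two
component-tone vectors and against the single-tone vectors themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .protocol import DF_GRID, DT_GRID
from .traces import ResponseTable

logger = logging.getLogger(__name__)


@dataclass
class PopulationVectors:
    """Significance-gated amplitude vectors per condition.

    ``twotone[i, j]`` is the vector for the (dF_i, dT_j) pair; ``center``
    and ``df_tone[i]`` are the single-tone vectors; ``linear_sum[i]`` is
    their elementwise sum (zero-forced vectors summed).  All vectors share
    one ROI ordering (``rois``).
    """

    rois: np.ndarray
    twotone: np.ndarray      # (9, 9, n_roi)
    center: np.ndarray       # (n_roi,)
    df_tone: np.ndarray      # (9, n_roi)
    linear_sum: np.ndarray   # (9, n_roi)


def build_population_vector(rt: ResponseTable, condition_id: int,
                            rois) -> np.ndarray:
    """Zero-forced population vector for one condition.

    Entry = clamped trial-mean amplitude where the (ROI, condition)
    response is significant, else exactly 0.
    """
    out = np.zeros(len(rois))
    for k, roi in enumerate(rois):
        if rt.is_significant(roi, condition_id):
            out[k] = max(rt.mean_amplitude(roi, condition_id), 0.0)
    return out


def linear_sum_vector(center_vec: np.ndarray, df_vec: np.ndarray) -> np.ndarray:
    """Elementwise sum of the two zero-forced single-tone vectors."""
    center_vec = np.asarray(center_vec, dtype=float)
    df_vec = np.asarray(df_vec, dtype=float)
    if center_vec.shape != df_vec.shape:
        raise ValueError(f"length mismatch: {center_vec.shape} vs "
                         f"{df_vec.shape}")
    return center_vec + df_vec


def population_vectors(rt: ResponseTable, rois=None) -> PopulationVectors:
    """Build all two-tone, single-tone and linear-sum vectors."""
    if rois is None:
        rois = rt.roi_ids
    rois = np.asarray(list(rois))
    grid = rt._grid()
    center_id, df_ids = rt.tone_condition_ids()
    center = build_population_vector(rt, center_id, rois)
    df_tone = np.stack([build_population_vector(rt, int(c), rois)
                        for c in df_ids])
    linear = np.stack([linear_sum_vector(center, df_tone[i])
                       for i in range(len(df_ids))])
    twotone = np.empty((grid.shape[0], grid.shape[1], len(rois)))
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            twotone[i, j] = build_population_vector(rt, int(grid[i, j]), rois)
    return PopulationVectors(rois=rois, twotone=twotone, center=center,
                             df_tone=df_tone, linear_sum=linear)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def pair_correlations(pv: PopulationVectors,
                      exclude_df_zero: bool = True) -> pd.DataFrame:
    """Correlation of each two-tone vector with its linear-sum and
    single-tone vectors, one row per (dF, dT) pair.

    ``r_single_tone`` averages the correlations with the center-tone and
    dF-tone vectors.  dF = 0 pairs are excluded by default (the two tones
    coincide in frequency there, so "two tones" degenerates to a louder
    single tone).
    """
    rows = []
    for i, df in enumerate(DF_GRID):
        if exclude_df_zero and np.isclose(df, 0.0):
            continue
        for j, dt in enumerate(DT_GRID):
            tt = pv.twotone[i, j]
            r_lin = _safe_corr(tt, pv.linear_sum[i])
            singles = [_safe_corr(tt, pv.center),
                       _safe_corr(tt, pv.df_tone[i])]
            singles = [s for s in singles if np.isfinite(s)]
            r_single = np.mean(singles) if singles else np.nan
            if np.isnan(r_lin):
                logger.info("zero-variance vector at dF=%.2f dT=%.0f; "
                            "pair skipped", df, dt)
            rows.append(dict(dF=df, dT=dt, r_linear_sum=r_lin,
                             r_single_tone=r_single,
                             timing="coincident" if dt == 0 else "shifted"))
    return pd.DataFrame(rows)


def correlate_conditions(pv: PopulationVectors,
                         exclude_df_zero: bool = True) -> pd.DataFrame:
    """Mean correlation per dT, averaged across dFs.

    Returns a frame indexed by dT with ``r_linear_sum`` (two-tone vs the
    linear sum of component-tone vectors) and ``r_single_tone`` (two-tone
    vs the individual tones, averaged over dFs and both tones).
    """
    pairs = pair_correlations(pv, exclude_df_zero=exclude_df_zero)
    return (pairs.groupby("dT")[["r_linear_sum", "r_single_tone"]]
            .mean().reset_index())


def compare_coincident_shifted(pair_table: pd.DataFrame):
    """Two-way ANOVA (area x timing) on pair-level correlations, with
    Tukey HSD contrasts.

    ``pair_table`` needs columns ``area``, ``timing`` and ``r`` (one row
    per dF-dT pair, e.g. 64 shifted + 8 coincident per area).  Returns a
    dict with the ANOVA table, F and p per effect, and the Tukey contrast
    table over the four area-timing groups.
    """
    df = pair_table.dropna(subset=["r"]).copy()
    counts = df.groupby(["area", "timing"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("every area x timing cell needs >= 2 pairs")
    model = ols("r ~ C(area) * C(timing)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    group = df["area"].astype(str) + ":" + df["timing"].astype(str)
    tukey = pairwise_tukeyhsd(df["r"].to_numpy(), group.to_numpy())
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return {
        "anova": anova,
        "F_area": float(anova.loc["C(area)", "F"]),
        "p_area": float(anova.loc["C(area)", "PR(>F)"]),
        "F_timing": float(anova.loc["C(timing)", "F"]),
        "p_timing": float(anova.loc["C(timing)", "PR(>F)"]),
        "F_interaction": float(anova.loc["C(area):C(timing)", "F"]),
        "p_interaction": float(anova.loc["C(area):C(timing)", "PR(>F)"]),
        "tukey": tukey_df,
    }


def two_tone_only_fraction(rt: ResponseTable, rois=None) -> dict:
    """Fraction of single-tone non-responsive neurons recruited by two tones.

    Among ROIs with no significant single-tone response, the fraction with
    a significant response to >= 1 two-tone condition, split by whether
    the recruiting pairs were coincident (dT = 0) only, shifted only, or
    both.  ``fraction`` is NaN when every ROI responds to a single tone.
    """
    if rois is None:
        rois = rt.roi_ids
    grid = rt._grid()
    center_id, df_ids = rt.tone_condition_ids()
    tone_ids = [center_id] + [int(c) for c in df_ids]
    dt0 = np.isclose(DT_GRID, 0.0)

    n_nonresp = 0
    n_coinc_only = n_shift_only = n_both = 0
    for roi in rois:
        if any(rt.is_significant(roi, c) for c in tone_ids):
            continue
        n_nonresp += 1
        sig = rt.twotone_sig_matrix(roi)
        coinc = sig[:, dt0].any()
        shift = sig[:, ~dt0].any()
        if coinc and shift:
            n_both += 1
        elif coinc:
            n_coinc_only += 1
        elif shift:
            n_shift_only += 1
    if n_nonresp == 0:
        return dict(fraction=np.nan, n_single_tone_nonresponsive=0,
                    coincident_only=0, shifted_only=0, both=0)
    frac = (n_coinc_only + n_shift_only + n_both) / n_nonresp
    return dict(fraction=frac, n_single_tone_nonresponsive=n_nonresp,
                coincident_only=n_coinc_only, shifted_only=n_shift_only,
                both=n_both)
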