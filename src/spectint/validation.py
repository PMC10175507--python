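"""Parameter-recovery and error-control benchmarks of the pipeline.

These routines run the full generator -> processing -> analysis chain on
populations with known ground truth and measure how well the analysis
recovers it: exactness of LI maps on noise-free data, LI error at
realistic trial-to-trial variability, empirical type-I error of the
trial-resampling nonlinearity test, false-positive rate of the
significance detector on pure-noise cells, and directional reproduction
of the area-level contrasts (coincidence-preference fractions, ensemble
correlation drop at coincidence, DSI ~ Bias_supp coupling).
"""

from __future__ import annotations

import numpy as np

from . import ensemble as ens
from . import fm as fm_mod
from . import interaction as ia
from .pipeline import compare_proportions
from .protocol import build_protocol
from .synth import make_cell, make_null_cell, make_population, \
    simulate_population
from .traces import process_dataset


def _run_population(cells, seed, include_fm):
    protocol = build_protocol(seed=seed, include_fm=include_fm)
    ts = simulate_population(cells, protocol, seed=seed)
    return process_dataset(ts, min_baseline_sd=1e-9)


def li_recovery_noise_free(seed: int, n_cells: int = 5) -> float:
    """Max |measured LI - true kernel| over valid cells, noise-free.

    The common transient-shape factor cancels in the LI ratio, so the
    recovery should be exact to float precision.
    """
    cells = [make_cell(template, seed=[seed, i, 0], trial_noise_cv=0.0,
                       baseline_sd=0.0, include_fm=False)
             for i, template in enumerate(
                 ["a2_coincident", "a1_asymmetric", "sublinear_uniform",
                  "linear", "a2_coincident"][:n_cells])]
    rt = _run_population(cells, seed, include_fm=False)
    worst = 0.0
    for roi, cell in zip(rt.roi_ids, cells):
        m = ia.build_interaction_map(rt, roi, run_significance=False)
        if m.valid.any():
            err = np.abs(m.li[m.valid] - cell.li_kernel[m.valid]).max()
            worst = max(worst, float(err))
    return worst


def li_recovery_noisy(seed: int, n_cells: int = 200,
                      trial_noise_cv: float = 0.2) -> float:
    """Median |LI error| across valid cells at the given trial CV."""
    half = n_cells // 2
    cells = (make_population("a2_coincident", half, seed,
                             trial_noise_cv=trial_noise_cv,
                             include_fm=False)
             + make_population("a1_asymmetric", n_cells - half, seed + 1,
                               trial_noise_cv=trial_noise_cv,
                               include_fm=False))
    rt = _run_population(cells, seed, include_fm=False)
    errors = []
    for roi, cell in zip(rt.roi_ids, cells):
        m = ia.build_interaction_map(rt, roi, run_significance=False)
        if m.valid.any():
            errors.extend(np.abs(m.li[m.valid]
                                 - cell.li_kernel[m.valid]).tolist())
    return float(np.median(errors))


def nonlinearity_type1_rate(seed: int, n_sims: int = 500,
                            alpha: float = 0.1) -> float:
    """Empirical rejection rate of the nonlinearity test under the null.

    Two-tone amplitudes are independent draws from the same sum
    distribution as the resampled component pairs, so any verdict other
    than "none" is a false positive.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        c = rng.normal(1.0, 0.2, 5)
        d = rng.normal(0.8, 0.2, 5)
        tt = rng.normal(1.0, 0.2, 5) + rng.normal(0.8, 0.2, 5)
        if ia.test_nonlinearity(tt, c, d, alpha=alpha) != ia.NONE:
            hits += 1
    return hits / n_sims


def significance_false_positive_rate(seed: int, n_cells: int = 200) -> dict:
    """Fraction of (cell, condition) pairs flagged significant on
    pure-noise cells, plus the per-cell any-condition rate."""
    cells = [make_null_cell() for _ in range(n_cells)]
    protocol = build_protocol(seed=seed, include_fm=False)
    ts = simulate_population(cells, protocol, seed=seed)
    rt = process_dataset(ts)
    cond_ids = rt.conditions["condition_id"].to_numpy(dtype=int)
    flags = rt.significance[:, cond_ids]
    return {
        "per_condition": float(flags.mean()),
        "per_cell": float(flags.any(axis=1).mean()),
        "n_cells": n_cells,
    }


def directional_reproduction(seed: int, n_cells: int = 300,
                             dsi_coupling: float = 0.3) -> dict:
    """Area-level contrasts between coincidence-tuned and asymmetric
    populations.

    Returns coincidence-preferring fractions with their chi-square
    comparison, the ensemble linear-sum correlation at coincident vs
    shifted timings for the coincidence-tuned population, and the
    DSI ~ bias correlations (suppressive coupled, facilitative not) for
    the asymmetric population.
    """
    pops = {}
    for name, template, fm_on, coupling in [
            ("a2", "a2_coincident", False, 0.0),
            ("a1", "a1_asymmetric", True, dsi_coupling)]:
        cells = make_population(template, n_cells, seed,
                                dsi_coupling=coupling, include_fm=fm_on)
        rt = _run_population(cells, seed, include_fm=fm_on)
        pops[name] = (cells, rt)

    # timing-preference fractions among two-tone-responsive neurons
    counts = {}
    for name, (_, rt) in pops.items():
        labels = [ia.classify_timing_preference(rt, roi).label
                  for roi in rt.roi_ids
                  if rt.twotone_sig_matrix(roi).any()]
        n = len(labels)
        k = sum(lab == "coincident_preferring" for lab in labels)
        counts[name] = (k, n)
    (k2, n2), (k1, n1) = counts["a2"], counts["a1"]
    chi2, p = compare_proportions(k2, n2, k1, n1)

    # ensemble correlation with the linear sum, coincident vs shifted
    _, rt2 = pops["a2"]
    pairs = ens.pair_correlations(ens.population_vectors(rt2))
    r_coinc = float(pairs.loc[pairs["timing"] == "coincident",
                              "r_linear_sum"].mean())
    r_shift = float(pairs.loc[pairs["timing"] == "shifted",
                              "r_linear_sum"].mean())

    # DSI ~ bias on the asymmetric population
    _, rt1 = pops["a1"]
    dsi, b_fac, b_supp = [], [], []
    for roi in rt1.roi_ids:
        if not rt1.twotone_sig_matrix(roi).any():
            continue
        tun = fm_mod.sweep_tuning(rt1, roi)
        if not tun.responsive_rates:
            continue
        m = ia.build_interaction_map(rt1, roi, run_significance=False)
        bias = fm_mod.linearity_bias(m.li, m.valid)
        dsi.append(tun.dsi_mid)
        b_fac.append(bias.bias_fac)
        b_supp.append(bias.bias_supp)
    r_supp, p_supp, n_supp = fm_mod.correlate_dsi_bias(dsi, b_supp)
    r_fac, p_fac, _ = fm_mod.correlate_dsi_bias(dsi, b_fac)

    return {
        "frac_coincident_a2": k2 / n2,
        "frac_coincident_a1": k1 / n1,
        "n_responsive_a2": n2,
        "n_responsive_a1": n1,
        "chi2": chi2,
        "p_fraction": p,
        "r_linear_sum_coincident": r_coinc,
        "r_linear_sum_shifted": r_shift,
        "r_dsi_bias_supp": r_supp,
        "p_dsi_bias_supp": p_supp,
        "r_dsi_bias_fac": r_fac,
        "p_dsi_bias_fac": p_fac,
        "n_dsi_cells": n_supp,
    }
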