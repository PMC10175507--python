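"""Synthetic two-photon experiments from ground-truth response models.

Each synthetic neuron is described by a :class:`GroundTruthCell`: its
single-tone tuning, a 9x9 "true" linearity-index kernel over the dF-dT
grid, FM-sweep amplitudes, GCaMP6s-like transient kinetics and noise
levels.  Two-tone amplitudes are obtained by inverting the LI definition,
T = L (1 + LI)/(1 - LI), so the downstream pipeline can be checked by
parameter recovery: on noise-free data the measured interaction map must
return the kernel exactly.

Trial traces are a unit-peak difference-of-exponentials calcium transient
scaled by the condition amplitude, with multiplicative lognormal
trial-to-trial variability and additive Gaussian baseline noise.  A
pixel-level forward model (cell + alpha x neuropil, plus deliberately
contaminated ring pixels) exercises the background-subtraction path.

One global seed expands to per-cell substreams by counter
(``default_rng([seed, cell_index])``), so changing the cell count never
reshuffles existing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import fm as _fm
from .protocol import (DF_GRID, DT_GRID, FM_RATES, KIND_FM, KIND_TONE,
                       KIND_TWOTONE, StimulusProtocol)
from .traces import RoiTraceSet

#: template LI values are capped here so the kernel inversion stays finite
LI_CAP = 0.95


@dataclass
class GroundTruthCell:
    """Ground-truth response model of one synthetic neuron.

    Amplitudes are in dF/F units; ``amp_df`` maps each dF (octaves) to the
    dF-tone response; ``li_kernel`` is the true 9x9 LI grid (rows dF, cols
    dT); ``sweep_amp`` maps (rate oct/s, direction) to the sweep response.
    """

    base_amp_center: float
    amp_df: dict
    li_kernel: np.ndarray
    sweep_amp: dict = field(default_factory=dict)
    tau_rise: float = 0.2
    tau_decay: float = 1.5
    trial_noise_cv: float = 0.2
    baseline_sd: float = 0.05

    def __post_init__(self):
        self.li_kernel = np.asarray(self.li_kernel, dtype=float)
        if self.li_kernel.shape != (len(DF_GRID), len(DT_GRID)):
            raise ValueError("li_kernel must be 9x9")
        if np.any(np.abs(self.li_kernel) > 1):
            raise ValueError("li_kernel values must lie in [-1, 1]")
        if self.base_amp_center < 0 or any(v < 0 for v in self.amp_df.values()):
            raise ValueError("amplitudes must be non-negative")
        if any(v < 0 for v in self.sweep_amp.values()):
            raise ValueError("sweep amplitudes must be non-negative")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("kinetics taus must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")

    def amp_df_at(self, dF: float) -> float:
        key = min(self.amp_df, key=lambda k: abs(k - dF))
        if abs(key - dF) > 1e-6:
            raise KeyError(f"no dF-tone amplitude for dF={dF}")
        return self.amp_df[key]


# ---------------------------------------------------------------------------
# kernel templates
# ---------------------------------------------------------------------------

def kernel_linear() -> np.ndarray:
    """All-zero kernel: every pair sums linearly."""
    return np.zeros((len(DF_GRID), len(DT_GRID)))


def kernel_sublinear_uniform(li: float = -0.3) -> np.ndarray:
    """Uniform sublinearity (e.g. global forward suppression)."""
    if not -1 <= li <= 0:
        raise ValueError("li must lie in [-1, 0]")
    return np.full((len(DF_GRID), len(DT_GRID)), float(li))


def kernel_a2_coincident(peak: float = 0.6, off: float = -0.3,
                         df_sigma: float = 0.7) -> np.ndarray:
    """Coincidence-tuned kernel: supralinear at dT = 0, sublinear elsewhere.

    The coincident column carries positive LI falling off with |dF|
    (Gaussian, SD ``df_sigma`` octaves) except at dF = 0, where two
    identical overlapping tones are just a louder single tone and the LI
    is zero.  All shifted columns carry ``off`` (< 0).
    """
    peak = min(float(peak), LI_CAP)
    if peak <= 0 or off >= 0:
        raise ValueError("need peak > 0 and off < 0")
    k = np.full((len(DF_GRID), len(DT_GRID)), float(off))
    j0 = int(np.argmin(np.abs(DT_GRID)))
    k[:, j0] = peak * np.exp(-DF_GRID ** 2 / (2 * df_sigma ** 2))
    k[int(np.argmin(np.abs(DF_GRID))), j0] = 0.0
    return k


def kernel_a1_asymmetric(fac_up: float = 0.5, fac_down: float = 0.25,
                         up_quadrant: str = "neg_neg",
                         down_quadrant: str = "neg_pos",
                         supp_up: float = -0.2, supp_down: float = -0.45,
                         fac_size: int = 3) -> np.ndarray:
    """Temporally asymmetric kernel with clustered supralinear quadrants.

    The Upward region (dF>0,dT>0 and dF<0,dT<0 quadrants) carries uniform
    sublinearity ``supp_up`` and the Downward region ``supp_down``;
    unequal values give the map a net suppressive asymmetry (the
    lateral-inhibition signature that predicts FM direction selectivity).
    A ``fac_size`` x ``fac_size`` supralinear cluster of LI ``fac_up``
    sits in the corner of one Upward-region quadrant (``neg_neg`` or
    ``pos_pos``, naming the (dF, dT) signs) and another of LI
    ``fac_down`` in one Downward-region quadrant (``neg_pos`` or
    ``pos_neg``), so the facilitative asymmetry is set independently of
    the suppressive one.  The dF = 0 row and dT = 0 column stay at zero.
    """
    fac_up = min(float(fac_up), LI_CAP)
    fac_down = min(float(fac_down), LI_CAP)
    if not (supp_up <= 0 and supp_down <= 0):
        raise ValueError("suppressive levels must be <= 0")
    if up_quadrant not in ("neg_neg", "pos_pos"):
        raise ValueError("up_quadrant must be an Upward-region quadrant")
    if down_quadrant not in ("neg_pos", "pos_neg"):
        raise ValueError("down_quadrant must be a Downward-region quadrant")
    k = np.zeros((len(DF_GRID), len(DT_GRID)))
    df = DF_GRID[:, None]
    dt = DT_GRID[None, :]
    k[((df > 0) & (dt > 0)) | ((df < 0) & (dt < 0))] = supp_up
    k[((df > 0) & (dt < 0)) | ((df < 0) & (dt > 0))] = supp_down
    rows = {"neg": slice(0, fac_size), "pos": slice(-fac_size, None)}
    for quad, fac in ((up_quadrant, fac_up), (down_quadrant, fac_down)):
        dfq, dtq = quad.split("_")
        k[rows[dfq], rows[dtq]] = fac
    return k


KERNEL_TEMPLATES = {
    "linear": kernel_linear,
    "sublinear_uniform": kernel_sublinear_uniform,
    "a2_coincident": kernel_a2_coincident,
    "a1_asymmetric": kernel_a1_asymmetric,
}


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def two_tone_amplitude_from_kernel(cell: GroundTruthCell, dF: float,
                                   dT: float) -> float:
    """Two-tone amplitude T implied by the cell's LI kernel.

    Inverts LI = (T - L)/(T + L) with L = center + dF-tone amplitude:
    T = L (1 + LI)/(1 - LI).  Recomputing LI from (T, L) returns the
    kernel value exactly.  LI = 1 with L > 0 is unrepresentable (T would
    be infinite); templates therefore cap LI at 0.95.
    """
    i = int(np.argmin(np.abs(DF_GRID - dF)))
    j = int(np.argmin(np.abs(DT_GRID - dT)))
    li = float(cell.li_kernel[i, j])
    l = cell.base_amp_center + cell.amp_df_at(DF_GRID[i])
    if li >= 1.0 and l > 0:
        raise ValueError("LI = 1 with L > 0 is unrepresentable; cap the "
                         "kernel below 1")
    if li <= -1.0:
        return 0.0
    return l * (1.0 + li) / (1.0 - li)


def ground_truth_amplitude(cell: GroundTruthCell, cond) -> float:
    """Noise-free response amplitude for one condition row."""
    kind = cond["kind"]
    if kind == KIND_TWOTONE:
        return two_tone_amplitude_from_kernel(cell, cond["dF"], cond["dT"])
    if kind == KIND_TONE:
        if cond["role"] == "center":
            return cell.base_amp_center
        return cell.amp_df_at(cond["dF"])
    if kind == KIND_FM:
        return cell.sweep_amp.get((float(cond["rate"]), cond["direction"]),
                                  0.0)
    raise ValueError(f"unknown condition kind {kind!r}")


def calcium_kernel(tau_rise: float, tau_decay: float, n_frames: int,
                   frame_rate: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials GCaMP transient."""
    t = np.arange(n_frames) / frame_rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def kernel_window_mean(cell: GroundTruthCell, window_frames: int,
                       frame_rate: float) -> float:
    """Mean of the transient kernel over a response window.

    The measured window-mean amplitude equals the true amplitude times
    this shape factor; divide by it to recover the ground truth.
    """
    k = calcium_kernel(cell.tau_rise, cell.tau_decay, window_frames,
                       frame_rate)
    return float(k.mean())


def synthesize_trial_traces(cell: GroundTruthCell,
                            protocol: StimulusProtocol,
                            seed) -> np.ndarray:
    """Simulate all trial snippets of one cell; shape (n_trials, n_frames).

    Each trial is amplitude x unit-peak transient placed at the onset
    frame, the amplitude multiplied by lognormal noise with the cell's CV,
    plus i.i.d. Gaussian baseline noise.
    """
    rng = np.random.default_rng(seed)
    n_trials = protocol.n_trials
    n_frames = protocol.n_frames
    onset = protocol.onset_frame
    k = calcium_kernel(cell.tau_rise, cell.tau_decay, n_frames - onset,
                       protocol.frame_rate)

    cond = protocol.conditions.set_index("condition_id")
    amps_by_cond = {cid: ground_truth_amplitude(cell, cond.loc[cid])
                    for cid in cond.index}
    amps = np.array([amps_by_cond[c]
                     for c in protocol.trials["condition_id"]])

    if cell.trial_noise_cv > 0:
        sigma2 = np.log1p(cell.trial_noise_cv ** 2)
        mult = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                             size=n_trials)
        amps = amps * mult
    traces = np.zeros((n_trials, n_frames))
    traces[:, onset:] = amps[:, None] * k[None, :]
    if cell.baseline_sd > 0:
        traces += rng.normal(0.0, cell.baseline_sd, size=traces.shape)
    return traces


def simulate_population(cells, protocol: StimulusProtocol,
                        seed: int) -> RoiTraceSet:
    """Simulate a population; per-cell substreams keyed by (seed, index)."""
    dff = np.stack([
        synthesize_trial_traces(cell, protocol, seed=[seed, i, 1])
        for i, cell in enumerate(cells)
    ])
    return RoiTraceSet(dff=dff, onset_frame=protocol.onset_frame,
                       frame_rate=protocol.frame_rate,
                       trials=protocol.trials.copy(),
                       conditions=protocol.conditions.copy())


def synthesize_pixel_traces(cell_trace: np.ndarray,
                            contamination_alpha: float = 0.9,
                            n_pixels: int = 20,
                            n_contaminated: int = 2,
                            neuropil_sd: float = 10.0,
                            pixel_noise_sd: float = 2.0,
                            contaminant_amp: float = 80.0,
                            baseline_f: float = 100.0,
                            seed=0):
    """Pixel-level forward model for background subtraction.

    A shared neuropil field contaminates the somatic signal: the measured
    cell trace is the true fluorescence plus ``contamination_alpha`` times
    the neuropil.  The background-ring pixels sample that same neuropil
    (plus per-pixel noise), so the mean of clean ring pixels estimates the
    contaminant and ``measured - alpha x background`` recovers the truth.
    ``n_contaminated`` pixels additionally carry large transient events
    that are confined to the ring (a neighbouring soma) and thus absent
    from the cell's contamination — including them corrupts the
    background estimate, which is what contaminated-pixel exclusion is
    for.

    Returns ``(measured, pixels, true_trace, contaminated_idx)`` where
    ``pixels`` has shape (n_pixels, n_frames).
    """
    if not 0 <= contamination_alpha <= 1:
        raise ValueError("contamination_alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    true_trace = np.asarray(cell_trace, dtype=float)
    n_frames = len(true_trace)

    neuropil = baseline_f + np.cumsum(rng.normal(0, neuropil_sd / 10.0,
                                                 n_frames))
    pixels = (neuropil[None, :]
              + rng.normal(0, pixel_noise_sd, size=(n_pixels, n_frames)))
    contaminated = rng.choice(n_pixels, size=n_contaminated, replace=False)
    for p in contaminated:
        n_events = rng.integers(3, 6)
        starts = rng.integers(0, max(n_frames - 30, 1), size=n_events)
        event = contaminant_amp * np.exp(-np.arange(30) / 10.0)
        for s in starts:
            seg = min(30, n_frames - s)
            pixels[p, s:s + seg] += event[:seg]
    measured = true_trace + contamination_alpha * neuropil
    return measured, pixels, true_trace, np.sort(contaminated)


def subtract_background(measured: np.ndarray, background: np.ndarray,
                        coeff: float = 0.9) -> np.ndarray:
    """F(t) = measured(t) - coeff x background(t)."""
    return np.asarray(measured, dtype=float) - coeff * np.asarray(background,
                                                                  dtype=float)


# ---------------------------------------------------------------------------
# population generators (study-condition defaults)
# ---------------------------------------------------------------------------

def _gaussian_tuning(rng, scale_lo=0.2, scale_hi=1.2):
    pref = rng.uniform(-1.0, 1.0)
    bw = rng.uniform(0.3, 0.8)
    scale = rng.uniform(scale_lo, scale_hi)
    return {float(dF): float(scale * np.exp(-(dF - pref) ** 2 / (2 * bw ** 2)))
            for dF in DF_GRID}


def make_cell(template: str, seed, *, trial_noise_cv: float = 0.2,
              baseline_sd: float = 0.05, dsi_coupling: float = 0.0,
              include_fm: bool = True, **overrides) -> GroundTruthCell:
    """Draw one randomized cell from a kernel template family.

    ``a2_coincident`` cells have a random coincidence-column LI peak in
    [0.4, 0.9] and off-coincidence suppression in [-0.5, -0.1];
    ``a1_asymmetric`` cells have independent Upward/Downward suppression
    levels in [-0.6, -0.05] and a supralinear cluster in a random
    quadrant.  With ``dsi_coupling`` > 0, the up/down sweep amplitudes are
    tied to the kernel's suppressive asymmetry (Bias_supp), the mechanism
    by which asymmetric lateral inhibition is thought to create FM
    direction selectivity; at 0 the sweep asymmetry is independent noise.
    """
    rng = np.random.default_rng(seed)
    base_center = rng.uniform(0.3, 1.2)
    amp_df = _gaussian_tuning(rng)

    if template == "a2_coincident":
        kern = kernel_a2_coincident(peak=rng.uniform(0.4, 0.9),
                                    off=rng.uniform(-0.5, -0.1),
                                    df_sigma=rng.uniform(0.5, 0.9))
        # many A2 neurons respond weakly to single tones but strongly to
        # coincident pairs; thin the single-tone amplitudes
        if rng.uniform() < 0.4:
            base_center *= 0.1
            amp_df = {k: v * 0.1 for k, v in amp_df.items()}
    elif template == "a1_asymmetric":
        kern = kernel_a1_asymmetric(
            fac_up=rng.uniform(0.1, 0.6),
            fac_down=rng.uniform(0.1, 0.6),
            up_quadrant=rng.choice(["neg_neg", "pos_pos"]),
            down_quadrant=rng.choice(["neg_pos", "pos_neg"]),
            supp_up=rng.uniform(-0.6, -0.05),
            supp_down=rng.uniform(-0.6, -0.05))
    elif template == "sublinear_uniform":
        kern = kernel_sublinear_uniform(li=rng.uniform(-0.5, -0.1))
    elif template == "linear":
        kern = kernel_linear()
    else:
        raise ValueError(f"unknown template {template!r}")

    sweep_amp = {}
    if include_fm:
        bias = _fm.linearity_bias(kern).bias_supp
        eta = rng.normal(0.0, 0.25)
        dsi_true = float(np.tanh(dsi_coupling * bias + eta))
        base_sweep = rng.uniform(0.3, 1.0)
        for rate in FM_RATES:
            # slower sweeps carry more energy -> larger responses
            rate_gain = (FM_RATES[0] / rate) ** 0.25
            u = base_sweep * rate_gain * (1.0 + dsi_true)
            d = base_sweep * rate_gain * (1.0 - dsi_true)
            sweep_amp[(rate, "up")] = max(u, 0.0)
            sweep_amp[(rate, "down")] = max(d, 0.0)

    cell = GroundTruthCell(base_amp_center=base_center, amp_df=amp_df,
                           li_kernel=kern, sweep_amp=sweep_amp,
                           trial_noise_cv=trial_noise_cv,
                           baseline_sd=baseline_sd)
    return replace(cell, **overrides) if overrides else cell


def make_null_cell(baseline_sd: float = 0.05) -> GroundTruthCell:
    """A cell with zero response to every stimulus: pure baseline noise.

    Used for empirical false-positive control of the significance
    detector.
    """
    return GroundTruthCell(base_amp_center=0.0,
                           amp_df={float(d): 0.0 for d in DF_GRID},
                           li_kernel=kernel_linear(), sweep_amp={},
                           trial_noise_cv=0.0, baseline_sd=baseline_sd)


def make_population(template: str, n_cells: int, seed: int,
                    **cell_kwargs) -> list:
    """Draw a population of cells; cell i uses substream (seed, i)."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return [make_cell(template, seed=[seed, i, 0], **cell_kwargs)
            for i in range(n_cells)]
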