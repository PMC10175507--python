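"""Shared settings for the analysis scripts.

Two synthetic populations stand in for the two imaged areas: an
"asymmetric" population (clustered supralinearity plus unequal Upward /
Downward suppression, sweep selectivity coupled to the suppressive
asymmetry) and a "coincidence" population (supralinear dT = 0 column,
sublinear elsewhere).  Sizes are kept at a few hundred cells so the whole
sequence runs in minutes on one core.
"""

from pathlib import Path

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

POPULATIONS = {
    # name -> (template, n_cells, include_fm, dsi_coupling)
    "asymmetric": ("a1_asymmetric", 150, True, 0.3),
    "coincidence": ("a2_coincident", 100, False, 0.0),
}


def dataset_path(name: str) -> Path:
    return RESULTS / "data" / f"{name}.h5"
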