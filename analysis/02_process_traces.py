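"""Quantify responses: amplitudes, AUC and significance per condition.

Reads the simulated datasets, applies the 3.3-SD dual-criterion
significance test within the condition-specific windows, and writes one
tidy response table per population.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import POPULATIONS, RESULTS, dataset_path

import numpy as np

from spectint.io import load_dataset
from spectint.traces import process_dataset


def main():
    out_dir = RESULTS / "responses"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in POPULATIONS:
        ts = load_dataset(dataset_path(name))
        rt = process_dataset(ts)
        np.save(out_dir / f"{name}.significance.npy", rt.significance)
        rt.trials.to_csv(out_dir / f"{name}.responses.csv", index=False)
        n_resp = int(rt.significance.any(axis=1).sum())
        print(f"{name}: {n_resp}/{rt.n_roi} ROIs "
              f"({100 * n_resp / rt.n_roi:.1f}%) responsive to >= 1 sound")


if __name__ == "__main__":
    main()
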