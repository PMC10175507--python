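"""Generate the synthetic two-tone / FM-sweep experiments.

Writes one HDF5 dataset per population (trial-aligned dF/F traces,
stimulus schedule, ground truth) plus a CSV export of the schedule.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import POPULATIONS, SEED, dataset_path

from spectint import build_protocol
from spectint.io import export_schedule_csv, save_dataset
from spectint.synth import make_population, simulate_population


def main():
    for name, (template, n_cells, fm_on, coupling) in POPULATIONS.items():
        cells = make_population(template, n_cells, SEED,
                                dsi_coupling=coupling, include_fm=fm_on)
        protocol = build_protocol(seed=SEED, include_fm=fm_on)
        ts = simulate_population(cells, protocol, seed=SEED)
        path = dataset_path(name)
        path.parent.mkdir(parents=True, exist_ok=True)
        save_dataset(path, ts, ground_truth=cells, seed=SEED)
        export_schedule_csv(path.with_suffix(".schedule.csv"), ts)
        print(f"{name}: {n_cells} cells x {ts.dff.shape[1]} trials "
              f"({ts.n_frames} frames each) -> {path}")


if __name__ == "__main__":
    main()
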