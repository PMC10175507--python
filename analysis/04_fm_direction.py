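"""FM-sweep direction selectivity and its link to map asymmetry.

For the population with sweep stimuli: responsive fraction per absolute
FM rate, DSI distributions, and the correlation of the single mid-rate
DSI with the facilitative and suppressive linearity-index biases
(Bonferroni-corrected per-rate variants included).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import POPULATIONS, RESULTS, dataset_path

import numpy as np
import pandas as pd

from spectint.fm import (correlate_dsi_bias, linearity_bias,
                         responsive_fraction_by_rate, sweep_tuning)
from spectint.interaction import build_interaction_map
from spectint.io import load_dataset
from spectint.pipeline import adjust_bonferroni
from spectint.protocol import FM_RATES
from spectint.traces import process_dataset


def main():
    out_dir = RESULTS / "fm"
    out_dir.mkdir(parents=True, exist_ok=True)
    name = next(n for n, spec in POPULATIONS.items() if spec[2])
    ts = load_dataset(dataset_path(name))
    rt = process_dataset(ts)

    frac = responsive_fraction_by_rate(rt, rt.roi_ids)
    print("responsive fraction by |rate|:",
          {r: round(v, 3) for r, v in frac.items()})

    rows = []
    for roi in rt.roi_ids:
        tun = sweep_tuning(rt, roi)
        if not tun.responsive_rates:
            continue
        if rt.twotone_sig_matrix(roi).any():
            m = build_interaction_map(rt, roi, run_significance=False)
            bias = linearity_bias(m.li, m.valid)
        else:
            continue
        row = dict(roi=roi, dsi_mid=tun.dsi_mid, bias_fac=bias.bias_fac,
                   bias_supp=bias.bias_supp)
        for r in FM_RATES:
            row[f"dsi_{r:g}"] = tun.dsi_per_rate.get(r, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / f"{name}.sweep_tuning.csv", index=False)

    stats_out = {"responsive_fraction_by_rate": frac,
                 "n_cells_both_stimuli": len(df)}
    for bias_col in ("bias_supp", "bias_fac"):
        r, p, n = correlate_dsi_bias(df["dsi_mid"], df[bias_col])
        stats_out[f"r_dsi_{bias_col}"] = r
        stats_out[f"p_dsi_{bias_col}"] = p
        per_rate_p = []
        for rate in FM_RATES:
            rr, pp, _ = correlate_dsi_bias(df[f"dsi_{rate:g}"], df[bias_col])
            per_rate_p.append(pp if np.isfinite(pp) else 1.0)
        stats_out[f"p_per_rate_{bias_col}_bonferroni"] = \
            adjust_bonferroni(per_rate_p, m=len(FM_RATES)).tolist()
        print(f"DSI ~ {bias_col}: r={r:.3f}, p={p:.3g} (n={n})")

    (out_dir / "stats.json").write_text(json.dumps(stats_out, indent=2,
                                                   default=float))


if __name__ == "__main__":
    main()
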