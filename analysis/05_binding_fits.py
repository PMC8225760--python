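#!/usr/bin/env python
"""Saturation-binding pKd recovery per receptor construct.

For each binding preset (SMO and FZD6, wild-type and 6.43 mutant),
generates 200 seeded noisy net-BRET saturation tables and refits them
with the construct's model (4-parameter for SMO, 3-parameter for FZD6),
summarizing the recovered affinities. The mutant-vs-wild-type contrast
mirrors the study design: the SMO F6.43P preset sits ~1.4 log units
weaker than SMO wild-type, while the two FZD6 constructs are
indistinguishable.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from classf import binding_models as bm
from classf import synthetic_data as syn

OUT = Path(__file__).resolve().parent.parent / "results"
N_TABLES = 200
SEED = 1
MODELS = {"smo_wt": 4, "smo_F643P": 4, "fzd6_wt": 3, "fzd6_P643F": 3}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for preset, n_params in MODELS.items():
        pkds = np.empty(N_TABLES)
        for i in range(N_TABLES):
            table = syn.generate_binding_table(
                syn.binding_preset(preset, seed=SEED * 100_003 + i)
            )
            fit = bm.fit_saturation(bm.net_bret(table), n_params=n_params)
            pkds[i] = fit.flags["pKd"]
        rows.append((preset, syn.BINDING_PRESETS[preset], n_params,
                     pkds.mean(), pkds.std(ddof=1), N_TABLES))
        print(f"{preset} ({n_params}p): recovered pKd "
              f"{pkds.mean():.3f} ± {pkds.std(ddof=1):.3f} (preset {syn.BINDING_PRESETS[preset]})")
    pd.DataFrame(
        rows, columns=["preset", "true_pKd", "n_params", "mean_pKd", "sd_pKd", "n_tables"]
    ).to_csv(OUT / "binding_recovery.csv", index=False)


if __name__ == "__main__":
    main()
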