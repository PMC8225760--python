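#!/usr/bin/env python
"""Dose-response model fits and nested-model selection.

Three exercises of the assay-model machinery:
1. a bell-shaped (biphasic) dose-response fit on a noisy synthetic
   recruitment curve, recovering both midpoints;
2. model selection on a saturating titration — the one-phase
   association wins the extra-sum-of-squares F-test and reports its
   plateau;
3. calibration of that F-test under a true linear model: over 1,000
   seeded runs the association model should be selected in about 5%
   of cases at alpha = 0.05.
"""

import json
from pathlib import Path

import numpy as np

from classf import binding_models as bm
from classf import synthetic_data as syn

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    bell_params = dict(p0=0.0, p1=20.0, p2=2.0, m1=-8.0, m2=-6.0, h1=1.0, h2=1.0,
                       concentrations=np.logspace(-10.5, -4.5, 13),
                       noise_sd=0.5, n_replicates=2)
    bell_fit = bm.fit_bell(syn.generate_dose_response("bell", bell_params, seed=SEED))
    report["bell"] = {"true_midpoints": [-8.0, -6.0],
                      "fitted_midpoints": [bell_fit.params["m1"], bell_fit.params["m2"]]}
    print(f"bell fit: midpoints {bell_fit.params['m1']:.2f} / {bell_fit.params['m2']:.2f} "
          f"(truth -8 / -6)")

    assoc_table = syn.generate_dose_response(
        "one_phase", dict(y0=0.02, plateau=0.30, k=0.006, doses=np.linspace(50, 900, 8),
                          noise_sd=0.01, n_replicates=4), seed=SEED)
    _, _, selected = bm.fit_titration(assoc_table)
    report["titration"] = {"selected": selected.model,
                           "plateau": selected.flags.get("plateau"),
                           "p_value": selected.flags.get("p_value")}
    print(f"saturating titration: {selected.model} selected "
          f"(plateau {selected.flags.get('plateau'):.3f}, p = {selected.flags.get('p_value'):.2e})")

    n_sel = 0
    n_runs = 1000
    for i in range(n_runs):
        table = syn.generate_dose_response(
            "linear", dict(intercept=0.02, slope=2e-4, doses=np.linspace(100, 900, 8),
                           noise_sd=0.01, n_replicates=1), seed=10_000 + i)
        _, _, chosen = bm.fit_titration(table)
        n_sel += chosen.model == "one_phase_association"
    rate = n_sel / n_runs
    report["f_test_calibration"] = {"alpha": 0.05, "n_runs": n_runs, "selected_fraction": rate}
    print(f"F-test calibration: association selected in {rate:.1%} of {n_runs} null runs")

    with open(OUT / "titration_selection.json", "w") as fh:
        json.dump(report, fh, indent=1)


if __name__ == "__main__":
    main()
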