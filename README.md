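# classf

Conformational and pharmacological analysis of class F GPCRs (the ten
Frizzleds and Smoothened), built around the role of transmembrane-helix-6
residue 6.43 — a proline in all FZDs, a phenylalanine in SMO. FZDs adopt a
kinked TM6 in the active-like state while SMO keeps it straight, with
consequences for the buried 7TM ligand cavity, the R6.32–W7.55 molecular
switch and its aromatic π–π extension, ligand binding affinity and
transducer recruitment.

The package is organised as an analysis project: every computation lives in
the library under `src/classf/`, and the numbered scripts under `analysis/`
drive it end to end on synthetic data, writing tables to `results/`.

## What it computes

**TM6 kink angle.** Per frame, the angle θ at the backbone nitrogen of
residue 6.43 (Ballesteros–Weinstein numbering) between rays to the backbone
nitrogens of 6.39 and 6.47; a straight helix scores ≈173°, a kinked one
lower. Series are smoothed with a 1 ns centered moving average for display;
summaries are the frame-pooled mean ± SD over all replicas.

**BW numbering and conservation.** Residue i of helix x is numbered
x.(50 + Δ), Δ counted in ungapped sequence space from the x.50 anchor
column of a class F alignment; column conservation is the modal non-gap
residue frequency.

**Interaction states.** Distance classifiers with inclusive cutoffs:
molecular switch closed iff min distance from the 6.32 side-chain nitrogens
(NE/NH1/NH2 for Arg, NZ for Lys) to the backbone O of 7.55 is ≤ 4 Å; the
Y6.40–Y2.51 hydroxyl bond at the same cutoff; aromatic π–π network edges
between ring centroids of members {3.43, 6.36, 6.40, 7.55} up to 7.5 Å.

**Buried-cavity volume.** A grid/ray method: grid points whose
nearest-heavy-atom distance lies in [2.6, 5.5] Å and with ≥ 9 of 14 lattice
rays (8 Å) blocked by an atom are cavity points; counting over frames gives
a frequency map, the 26-connected component at isovalue 3 containing a seed
point is the tracked pocket, and per-frame volume is (cavity points in the
component) × spacing³. Validated against a Monte-Carlo oracle applying the
same rule at uniform random points.

**Assay models.** Net BRET (control-well subtraction), %ΔBRET with vehicle
correction, surface-expression normalization and dual-reporter fold change
as exact arithmetic; saturation binding y = y₀ + A·C/(K_d + C) (3-parameter)
or y = y₀ + A·Cʰ/(K_dʰ + Cʰ) (4-parameter) reporting pK_d = −log₁₀ K_d with
asymptotic SE; a two-logistic bell model for biphasic dose–response;
straight-line vs one-phase-association titration fits selected by the
extra-sum-of-squares F-test, F = ((SS₁−SS₂)/(df₁−df₂))/(SS₂/df₂), α = 0.05.

**Synthetic data.** Ideal α-helices bent by an exact rotation so the
measured vertex angle hits a prescribed target; four-replica ensembles
([500, 250, 250, 250] ns at 100 ps/frame) whose per-frame angle follows a
stationary AR(1) law around a receptor preset (FZD6-like 158.5 ± 4.5°,
SMO-like 168.4 ± 4.2°, mutants swapped); a 7-helix bundle with a buried
central channel; noisy saturation/dose–response plate tables with
per-receptor pK_d presets (6.87, 5.44, 6.45, 6.28).

## Worked example

```python
from classf import synthetic_data as syn, binding_models as bm
from classf.conformation import tm6_kink_series, summarize_angles

helix = syn.HelixSpec()
trajs = syn.generate_trajectory(helix, syn.kink_preset("fzd6"),
                                syn.EnsembleSpec(seed=1))
resmap = syn.helix_residue_map(helix)
summary = summarize_angles([tm6_kink_series(t, resmap) for t in trajs])
print(f"{summary.mean_deg:.2f} +/- {summary.sd_deg:.2f} deg over {summary.n_frames} frames")

fit = bm.fit_saturation(bm.net_bret(syn.generate_binding_table(
    syn.binding_preset("smo_wt", seed=1))), n_params=4)
print(f"pKd {fit.flags['pKd']:.2f} +/- {fit.flags['pKd_se']:.2f}")
```

prints

```
158.46 +/- 4.48 deg over 12504 frames
pKd 6.87 +/- 0.03
```

— the pooled TM6 kink angle of the FZD6-like ensemble (12,504 frames across
four replicas) agreeing with the generating law 158.5 ± 4.5°, and a single
noisy binding table refit recovering the SMO wild-type affinity preset
(pK_d 6.87) within its standard error.

The same analyses at full size, with CSV outputs under `results/`:

```sh
python analysis/01_simulate_ensembles.py   # 126 poses/system at 1 frame/10 ns
python analysis/02_kink_angles.py          # angle series + pooled summaries
python analysis/03_interaction_states.py   # switch / aromatic-network states
python analysis/04_pocket_volumes.py       # cavity volumes + Monte-Carlo check
python analysis/05_binding_fits.py         # pKd recovery per construct
python analysis/06_titration_selection.py  # bell fit, F-test selection + calibration
```

A `classf` console script exposes the same steps
(`classf simulate | kink-angle | switch | network | pocket | fit-binding | report`).

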