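# Methods

## The TM6 kink metric

The conformational readout throughout the package is a three-point angle:
for a vertex residue v (BW 6.43 by default), θ is the interior angle at the
backbone nitrogen of v between rays to the backbone nitrogens of v−4 and
v+4 (6.39 and 6.47). On the package's ideal helix (1.5 Å rise, 100°
twist per residue, N atoms at radius 1.5 Å) the unkinked value is
173.39°, set by the helical wobble of the N positions; kinking lowers it.
The metric deliberately avoids full helix-axis fitting (HELANAL-style
per-residue bend analysis): the three-nitrogen angle is the quantity the
downstream statistics are defined on, and that is what is implemented.

Per-frame series may be smoothed with a centered moving average whose
window is `round(window_ns / frame_interval)` frames, forced odd, with
truncated edges so the series length is preserved (plotting parity with
the raw trace). Smoothing is a display device only: all summaries (pooled
mean, SD with denominator n−1) are computed on raw angles, pooled
frame-weighted across replicas so a 500 ns replica counts twice as much
as a 250 ns one. Per-replica means are reported alongside so a
replica-weighted reading can be recovered.

## Synthetic ensembles

The generator emulates an MD ensemble at the level the analyses consume:
an idealized TM6 backbone whose vertex angle fluctuates with prescribed
statistics.

* Geometry: backbone atoms (N, CA, C, O; offsets are a geometric
  stand-in, not a rotamer library) on a circular helix about z. A kink is
  applied by rigidly rotating all residues after the vertex about an axis
  through the vertex N, perpendicular to the local helix axis (estimated
  from the v±4 nitrogen chord) — so atoms up to the vertex are exactly
  untouched. The vertex angle is a sinusoid in the rotation magnitude;
  the solver bisects the monotone branch starting at the angle-maximizing
  rotation (90° wide) to 0.01° tolerance and, of the two symmetric
  solutions, keeps the one nearest zero rotation so an unkinked target is
  a fixed point.
* Dynamics: per frame the target angle follows a stationary AR(1),
  a_t = μ + φ(a_{t−1} − μ) + ε_t with ε ~ N(0, σ√(1−φ²)) and
  a_0 ~ N(μ, σ), so the marginal is N(μ, σ²) at every t. The default
  φ = 0 (white noise) makes the frame-pooled mean an unbiased estimate of
  μ with standard error σ/√n; positive φ adds realistic persistence
  without changing the marginal. Targets beyond the geometrically
  reachable angle range (or 180°) are clipped to it; with the receptor
  presets this touches only the far upper tail (≲0.5% of SMO-like frames,
  biasing the pooled mean by well under 0.05°).
* Presets: FZD6-like 158.5 ± 4.5° (kinked), SMO-like 168.4 ± 4.2°
  (straight). The 6.43 point mutants are modelled with the opposite
  phenotype's law — no separate summary statistics exist for them, and
  the qualitative finding they encode is precisely the phenotype swap.
* Replica layout: [500, 250, 250, 250] ns at 100 ps/frame (12,504 frames).
  The saving interval is a modelling choice — it makes the 1 ns smoothing
  window a 10-frame boxcar and keeps ensembles desk-scale — since only
  the replica durations, not the frame rate, are fixed by the study
  design being emulated.
* Subsampling: one frame per Δ ns across replicas, replica 1 contributing
  t = 0, Δ, …, T₁ (inclusive) and continuation replicas t = Δ, …, Tᵢ
  (exclusive, their t = 0 duplicating the branch point). The count is
  Σ floor(Tᵢ/Δ) + 1, i.e. 126 poses for the default layout at Δ = 10 ns.
  Δ must be commensurate with the frame interval; it need not divide the
  replica length (the trailing remainder simply yields no frame).

What the generator does **not** emulate: side-chain rotamers, solvent and
membrane, force-field physics, correlated motions beyond AR(1), drift or
rare-event transitions. Passing tests therefore demonstrate that the
measurement pipeline is correct and unbiased under the stated statistical
law — not that real trajectories satisfy that law.

## BW numbering

Offsets from the x.50 anchor are counted in each sequence's own ungapped
residue space, never in alignment columns, so an insertion in one
paralogue cannot shift another's numbering. Helix spans and anchor
columns are configuration (the toy fixtures define their own); a gap at
an anchor column is an error for that sequence. Conservation is modal
non-gap residue frequency — the simplest score matching a shaded
alignment-conservation track; entropy scoring is out of scope.

## Interaction-state classification

All criteria are geometric distances with inclusive cutoffs; no angular
hydrogen-bond term is applied because the states being reproduced are
defined by distance alone (≤ 4 Å for hydrogen bonds, ≤ 7.5 Å for π–π).
The switch uses the minimum over the 6.32 side-chain nitrogens
({NE, NH1, NH2} for Arg, {NZ} for Lys) to the 7.55 backbone O. Ring
centroids are unweighted means over one atom set per residue (9-atom
indole for Trp, 6-membered ring for Phe/Tyr) — a single centroid per
residue matching the single-distance treatment of the network; π–π
distances are centroid–centroid, recorded as such in CLI output since a
closest-ring-atom convention would read systematically shorter.
Non-aromatic members (A6.40/F3.43 in SMO-like inputs) are dropped with a
warning. Synthetic fixtures may carry a single pseudo-centroid atom
("CEN") per residue in place of a full ring.

## Buried-cavity volumes

The pocket tracker is a self-contained grid method, not a reimplementation
of the alpha-sphere/Voronoi machinery of the fpocket suite, and no
equivalence with it is claimed. A point is a cavity point when its
nearest-heavy-atom distance lies in [d_min, d_max] = [2.6, 5.5] Å (closer
is clash, farther is bulk) and it is buried: of 14 lattice rays (6 axial,
8 diagonal) of 8 Å, at least 9 intersect an atom sphere of radius 2.0 Å.
The frequency map counts, per grid point, the frames in which it is a
cavity point; isovalue 3 ("cavity in ≥ 3 frames") thresholds it, and the
26-connected component containing the seed point (or the nearest
qualifying point within 3 Å) is the tracked pocket. Volume is point count
× spacing³ at 0.8 Å spacing.

Correctness is checked against a Monte-Carlo oracle that applies the
identical classification rule at uniform random points in the same
bounding box: on the toy bundle the grid volume agrees within ~2% at 10⁶
samples, and halving the spacing changes the volume by <1%, so the
discretization — the only thing the grid adds — is far inside the 20%/10%
bands the tests enforce. The toy 7-helix bundle (ring radius 7.5 Å,
30-residue helices) is sized so the channel wall sits ~5.2 Å from the
axis, inside the distance band, while inter-helix gaps are below d_min
and stay closed.

## Assay models and fitting

The plate arithmetic (net BRET as control-well mean subtraction, %ΔBRET
= (stimulated − basal)/basal × 100 with vehicle-mean correction,
surface-expression normalization against a reference condition,
firefly/renilla fold change over the vehicle mean) is exact and is tested
to machine precision.

Nonlinear fits are unweighted least squares on untransformed responses
(no variance model is assumed beyond homoscedastic noise, which is also
what the generator produces). Saturation fits parameterize log₁₀K_d — the
natural scale of plate-reader titrations — and report pK_d = −log₁₀K_d
with the asymptotic SE from the residual-scaled inverse J'J; multi-start
initialization places log₁₀K_d at the quartiles of the observed
log-concentrations, and fits whose K_d leaves the concentration range by
>100× are flagged. The 3-parameter model is the baseline hyperbola
(y₀, A, K_d); the 4-parameter model frees the Hill slope (bounds
[0.1, 10]); neither fixes a plateau, and the exported parameterization
makes the convention explicit.

The bell model is a sum of two logistics over x = log₁₀C,
y = p₀ + (p₁−p₀)/(1+10^((m₁−x)h₁)) + (p₂−p₁)/(1+10^(−(x−m₂)h₂)),
with the fall midpoint parameterized as m₂ = m₁ + gap, gap ≥ 0, so the
rise precedes the fall by construction. The functional form is the
package's choice — "bell-shaped" fixes only the shape — and data-driven
initialization (baseline, peak, tail, half-max crossings) with jittered
restarts recovers noise-free parameters to 10⁻⁴. Monotone data collapse
the fall amplitude toward zero and are flagged `degenerate_fall`.

Titration curves are fitted to a straight line and to the one-phase
association y = Y₀ + (P − Y₀)(1 − e^(−Kx)). The association fit uses
variable projection: for fixed K the model is linear in (Y₀, P), so the
residual SS is profiled over K on a log grid plus Brent refinement. K is
not sign-constrained: with K of either sign the family curves both ways
around a line, the nested line being the K → 0 limit, which (a)
guarantees the association SS never exceeds the linear SS and (b) keeps
the extra-sum-of-squares F-test two-sided — with K forced positive the
family can only curve one way and the realized type-I rate halves. As
implemented, the association model is selected under a true linear model
in 4.7% of 1,000 seeded runs at α = 0.05. The F-test itself is
F = ((SS_s − SS_c)/(df_s − df_c))/(SS_c/df_c) with p from
F(df_s−df_c, df_c); equal sums of squares select the simple model.

Binding presets carry per-construct pK_d (SMO 6.87, SMO F6.43P 5.44,
FZD6 6.45, FZD6 P6.43F 6.28), amplitude 0.3 and baseline 0.1 net-BRET
units (typical magnitudes for such titrations), Hill slope 1, noise SD
5% of amplitude, 10 concentrations spanning pK_d ± 2 log units in
duplicate with 4 acceptor-free control wells.

## Problem sizes and determinism

The standard analyses run a full 12,504-frame four-replica ensemble per
system (seconds, vectorized), 200 tables per binding preset, 1,000 null
titrations for the F-test calibration, and 10⁶ Monte-Carlo samples for
the pocket oracle. Every stochastic step takes an explicit integer seed
through `numpy.random.default_rng`; rerunning any generator, pipeline or
script with the same seed reproduces its output bit for bit.

## Known limitations

* The kinked-helix generator bends a single helix at one vertex; it does
  not model the coupled rearrangement of a 7TM bundle, so switch/network
  analyses run on purpose-built fixtures rather than on the kink
  ensembles.
* Pocket volumes depend on the classification constants (distance band,
  ray length, atom radius, buriedness threshold); they are internally
  consistent and oracle-validated but not comparable in absolute terms to
  alpha-sphere methods.
* The asymptotic SEs of nonlinear fits understate uncertainty at small n
  or near parameter bounds; the recovery studies average point estimates
  and do not rely on the SEs.
* Mutant kink presets reuse the opposite wild-type law; any quantitative
  mutant-specific dynamics are out of scope.
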