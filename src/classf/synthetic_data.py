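"""Synthetic inputs emulating the study's MD ensembles and plate-reader data.

Three families of generators live here:

* ideal and kinked α-helices plus multi-replica trajectory ensembles whose
  TM6 vertex angle fluctuates around a prescribed mean/SD (stationary AR(1)
  law), standing in for the receptor MD trajectories;
* a toy 7-helix bundle enclosing a buried central channel, standing in for
  the 7TM core cavity;
* noisy assay tables (saturation binding, bell-shaped dose-response,
  one-phase-association / linear titrations) emulating BRET plate-reader
  output.

All generators are pure functions of their spec and seed.

The kink presets carry the receptor summary statistics used throughout the
analyses: a kinked TM6 for FZD6 (158.5 ± 4.5°) versus a straighter one for
SMO (168.4 ± 4.2°); the 6.43 point mutants swap the phenotypes. Binding
presets carry the per-receptor BODIPY-cyclopamine affinities (pKd 6.87,
5.44, 6.45, 6.28 for SMO wild-type, SMO F6.43P, FZD6 wild-type and FZD6
P6.43F respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bw_numbering import ResidueMap
from .conformation import three_point_angle, three_point_angles
from .structure_io import Frame, StructureError, Trajectory

__all__ = [
    "HelixSpec",
    "KinkSpec",
    "EnsembleSpec",
    "BindingSpec",
    "KINK_PRESETS",
    "BINDING_PRESETS",
    "kink_preset",
    "binding_preset",
    "build_ideal_helix",
    "helix_residue_map",
    "apply_kink",
    "ar1_angle_series",
    "generate_trajectory",
    "subsample_frames",
    "build_toy_bundle",
    "generate_binding_table",
    "generate_dose_response",
]


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------

#: (radius Å, phase deg, axial shift Å) per backbone atom of an idealized
#: α-helix about its axis; values are a geometric stand-in, not a rotamer
#: library.
DEFAULT_ATOM_OFFSETS: dict[str, tuple[float, float, float]] = {
    "N": (1.5, -27.5, -0.9),
    "CA": (2.3, 0.0, 0.0),
    "C": (1.7, 26.0, 0.55),
    "O": (2.0, 40.0, 0.75),
}


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of an idealized α-helix (axis along z).

    ``n_res`` must be ≥ 9 so a mid-helix vertex has the ±4 flanking
    residues the kink metric needs.
    """

    n_res: int = 21
    rise_per_res: float = 1.5
    twist_per_res: float = 100.0
    atom_offsets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ATOM_OFFSETS)
    )
    residue_start: int = 1
    residue_name: str = "ALA"
    chain: str = "A"
    pseudo_sidechain: bool = False
    pseudo_radius: float = 3.5

    def __post_init__(self) -> None:
        if self.n_res < 9:
            raise ValueError("helix needs at least 9 residues (vertex ± 4)")
        if self.rise_per_res <= 0:
            raise ValueError("rise per residue must be positive")


def build_ideal_helix(spec: HelixSpec) -> Frame:
    """Deterministic backbone helix about the z axis with the stated
    rise/twist; optionally one pseudo side-chain centroid atom ("CEN")
    per residue at a fixed radial offset."""
    names, res_idx, res_names, chains, coords = [], [], [], [], []
    offsets = dict(spec.atom_offsets)
    if spec.pseudo_sidechain:
        offsets["CEN"] = (spec.pseudo_radius, 0.0, 0.8)
    for i in range(spec.n_res):
        theta = math.radians(i * spec.twist_per_res)
        z = i * spec.rise_per_res
        for name, (r, phase, dz) in offsets.items():
            ang = theta + math.radians(phase)
            names.append(name)
            res_idx.append(spec.residue_start + i)
            res_names.append(spec.residue_name)
            chains.append(spec.chain)
            coords.append((r * math.cos(ang), r * math.sin(ang), z + dz))
    return Frame(
        np.array(names, dtype=object),
        np.array(res_idx, dtype=int),
        np.array(res_names, dtype=object),
        np.array(chains, dtype=object),
        np.array(coords, dtype=float),
    )


def helix_residue_map(
    spec: HelixSpec, vertex_bw: str = "6.43", sequence_id: str = "synthetic"
) -> ResidueMap:
    """BW map for a generated helix: the mid-helix residue is the vertex
    position (6.43 by default) and neighbours are offset by ±1."""
    helix, num = vertex_bw.split(".")
    vertex_num = int(num)
    vertex_res = spec.residue_start + spec.n_res // 2
    to_bw = {
        spec.residue_start + i: f"{helix}.{vertex_num + (spec.residue_start + i - vertex_res)}"
        for i in range(spec.n_res)
    }
    return ResidueMap(sequence_id, to_bw=to_bw)


# ---------------------------------------------------------------------------
# Kink machinery
# ---------------------------------------------------------------------------

class KinkError(ValueError):
    """Unreachable kink target or invalid vertex."""


def _n_atom_position(frame: Frame, residue: int) -> np.ndarray:
    mask = (frame.residue_indices == residue) & (frame.names == "N")
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise KinkError(f"residue {residue}: expected one backbone N, found {len(idx)}")
    return frame.coords[int(idx[0])]


@dataclass(frozen=True)
class _KinkGeometry:
    """Rotation setup for bending a helix at a vertex residue."""

    origin: np.ndarray          # vertex backbone N
    axis: np.ndarray            # unit rotation axis (helix axis x radial)
    u: np.ndarray               # N(vertex-4) - N(vertex), fixed
    w: np.ndarray               # N(vertex+4) - N(vertex), rotates
    downstream: np.ndarray      # bool mask of atoms rotated with the kink
    phi_max: float              # rotation (rad) maximizing the vertex angle
    angle_max: float            # maximal reachable vertex angle (deg)


def _kink_geometry(frame: Frame, vertex_residue: int) -> _KinkGeometry:
    n_minus = _n_atom_position(frame, vertex_residue - 4)
    n_vertex = _n_atom_position(frame, vertex_residue)
    n_plus = _n_atom_position(frame, vertex_residue + 4)

    # local pre-kink helix axis from the 8-residue chord; radial direction
    # from the centroid of the nine flanking backbone N atoms
    h = n_plus - n_minus
    h = h / np.linalg.norm(h)
    flank = [
        _n_atom_position(frame, r)
        for r in range(vertex_residue - 4, vertex_residue + 5)
    ]
    centroid = np.mean(flank, axis=0)
    radial = n_vertex - centroid
    radial = radial - np.dot(radial, h) * h
    if np.linalg.norm(radial) < 1e-8:
        raise KinkError("degenerate helix geometry: vertex N on the local axis")
    radial = radial / np.linalg.norm(radial)
    axis = np.cross(h, radial)
    axis = axis / np.linalg.norm(axis)

    u = n_minus - n_vertex
    w = n_plus - n_vertex

    # vertex angle as a function of the rotation phi is sinusoidal:
    # cos(angle) = (A + C cos(phi - phi0)) / (|u||w|); locate its maximum
    w_par = np.dot(w, axis) * axis
    w_perp = w - w_par
    a_const = float(np.dot(u, w_par))
    b_cos = float(np.dot(u, w_perp))
    b_sin = float(np.dot(u, np.cross(axis, w_perp)))
    c_amp = math.hypot(b_cos, b_sin)
    phi0 = math.atan2(b_sin, b_cos)
    norm = np.linalg.norm(u) * np.linalg.norm(w)
    # angle maximal where cos(angle) minimal: phi - phi0 = pi
    phi_max = phi0 + math.pi
    if phi_max > math.pi:
        phi_max -= 2 * math.pi
    cos_min = (a_const - c_amp) / norm
    angle_max = math.degrees(math.acos(np.clip(cos_min, -1.0, 1.0)))

    downstream = frame.residue_indices > vertex_residue
    return _KinkGeometry(n_vertex, axis, u, w, downstream, phi_max, angle_max)


def _angles_at_rotation(geom: _KinkGeometry, phi: np.ndarray) -> np.ndarray:
    """Vertex angle (deg) after rotating the downstream flank N by phi (rad)."""
    phi = np.asarray(phi, dtype=float)
    w_par = np.dot(geom.w, geom.axis) * geom.axis
    w_perp = geom.w - w_par
    cross = np.cross(geom.axis, w_perp)
    w_rot = (
        w_par[None, :]
        + np.cos(phi)[..., None] * w_perp[None, :]
        + np.sin(phi)[..., None] * cross[None, :]
    )
    u = geom.u
    cosang = (w_rot @ u) / (np.linalg.norm(u) * np.linalg.norm(geom.w))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _solve_rotations(
    geom: _KinkGeometry, targets: np.ndarray, tol_deg: float = 0.005
) -> np.ndarray:
    """Bisection for the rotation magnitudes reproducing the target vertex
    angles, on the monotone branch starting at the angle-maximizing
    rotation (90° wide bracket)."""
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    lo = np.full_like(targets, geom.phi_max)
    hi = np.full_like(targets, geom.phi_max + math.pi / 2)
    angle_lo = _angles_at_rotation(geom, lo)
    angle_hi = _angles_at_rotation(geom, hi)
    if np.any(targets > angle_lo + 1e-9) or np.any(targets < angle_hi - 1e-9):
        bad = targets[(targets > angle_lo + 1e-9) | (targets < angle_hi - 1e-9)]
        raise KinkError(
            f"target angle(s) {bad} deg outside the reachable range "
            f"[{float(angle_hi.min()):.2f}, {geom.angle_max:.2f}] deg"
        )
    # angle decreases monotonically from lo to hi over this bracket
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ang = _angles_at_rotation(geom, mid)
        above = ang > targets
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
        if np.max(np.abs(ang - targets)) < tol_deg * 0.1:
            break
    phi = 0.5 * (lo + hi)
    # the vertex angle is symmetric about phi_max; of the two equivalent
    # rotations pick the one nearest zero, so an unkinked target leaves an
    # ideal helix (essentially) unchanged
    mirrored = 2.0 * geom.phi_max - phi
    return np.where(np.abs(mirrored) < np.abs(phi), mirrored, phi)


def _rotate_downstream(
    frame: Frame, geom: _KinkGeometry, phi: float, time_ps: float | None = None
) -> Frame:
    coords = frame.coords.copy()
    d = coords[geom.downstream] - geom.origin
    k = geom.axis
    rotated = (
        math.cos(phi) * d
        + math.sin(phi) * np.cross(k, d)
        + (1 - math.cos(phi)) * np.outer(d @ k, k)
    )
    coords[geom.downstream] = geom.origin + rotated
    return frame.with_coords(coords, time_ps=time_ps)


def apply_kink(frame: Frame, vertex_residue: int, target_angle_deg: float) -> Frame:
    """Bend a helix so the three-point N angle at (vertex-4, vertex,
    vertex+4) equals ``target_angle_deg`` within 0.01°.

    Residues after the vertex are rigidly rotated about an axis through
    the vertex backbone N, perpendicular to the local helix axis; atoms
    up to and including the vertex are untouched (exact equality).
    Targets outside the reachable image raise :class:`KinkError`.
    """
    if not (90.0 < target_angle_deg <= 180.0):
        raise KinkError(f"target angle {target_angle_deg} deg outside (90, 180]")
    geom = _kink_geometry(frame, vertex_residue)
    phi = float(_solve_rotations(geom, np.array([target_angle_deg]))[0])
    bent = _rotate_downstream(frame, geom, phi)
    achieved = three_point_angle(
        _n_atom_position(bent, vertex_residue - 4),
        _n_atom_position(bent, vertex_residue),
        _n_atom_position(bent, vertex_residue + 4),
    )
    if abs(achieved - target_angle_deg) > 0.01:
        raise KinkError(
            f"kink solver did not converge: achieved {achieved:.4f} deg "
            f"for target {target_angle_deg:.4f} deg"
        )
    return bent


# ---------------------------------------------------------------------------
# Trajectory ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinkSpec:
    """Target law of the per-frame vertex angle: stationary AR(1) around
    ``angle_mean_deg`` with marginal SD ``angle_sd_deg``."""

    angle_mean_deg: float
    angle_sd_deg: float
    vertex_bw: str = "6.43"
    ar1_phi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_mean_deg <= 180.0):
            raise ValueError("angle mean must lie in (0, 180]")
        if self.angle_sd_deg < 0:
            raise ValueError("angle SD must be non-negative")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")


#: Receptor kink presets (mean, SD in degrees). The point mutants carry the
#: opposite wild-type phenotype (straight-like / kinked-like).
KINK_PRESETS: dict[str, tuple[float, float]] = {
    "fzd6": (158.5, 4.5),
    "smo": (168.4, 4.2),
    "fzd6_P643F": (168.4, 4.2),
    "smo_F643P": (158.5, 4.5),
}


def kink_preset(name: str, **overrides) -> KinkSpec:
    if name not in KINK_PRESETS:
        raise KeyError(f"unknown kink preset {name!r}; options: {sorted(KINK_PRESETS)}")
    mean, sd = KINK_PRESETS[name]
    return replace(KinkSpec(mean, sd), **overrides) if overrides else KinkSpec(mean, sd)


@dataclass(frozen=True)
class EnsembleSpec:
    """Replica layout of a synthetic ensemble.

    Defaults mirror the study's four-replica design: one 500 ns replica
    plus three 250 ns replicas, saved every 100 ps.
    """

    replica_lengths_ns: tuple[float, ...] = (500.0, 250.0, 250.0, 250.0)
    frame_interval_ps: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.replica_lengths_ns):
            raise ValueError("replica lengths must be positive")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be positive")

    def n_frames(self, replica: int) -> int:
        length_ps = self.replica_lengths_ns[replica] * 1000.0
        return int(round(length_ps / self.frame_interval_ps)) + 1  # inclusive of t=0


def ar1_angle_series(kink: KinkSpec, ens: EnsembleSpec) -> list[np.ndarray]:
    """Per-replica target-angle sequences: a_t = mu + phi (a_{t-1} - mu) +
    eps_t with eps ~ N(0, sigma*sqrt(1-phi^2)) and a_0 ~ N(mu, sigma),
    so the marginal law is N(mu, sigma^2) for every t."""
    rng = np.random.default_rng(ens.seed)
    mu, sigma, phi = kink.angle_mean_deg, kink.angle_sd_deg, kink.ar1_phi
    out = []
    for r in range(len(ens.replica_lengths_ns)):
        n = ens.n_frames(r)
        if sigma == 0.0:
            out.append(np.full(n, mu))
            continue
        eps = rng.standard_normal(n)
        a = np.empty(n)
        a[0] = mu + sigma * eps[0]
        innov_sd = sigma * math.sqrt(1.0 - phi * phi)
        for t in range(1, n):
            a[t] = mu + phi * (a[t - 1] - mu) + innov_sd * eps[t]
        out.append(a)
    return out


def generate_trajectory(
    helix: HelixSpec, kink: KinkSpec, ens: EnsembleSpec
) -> list[Trajectory]:
    """One synthetic trajectory per replica, with per-frame coordinates
    built by bending the ideal helix to the AR(1) target angles.

    Target draws falling outside the geometrically reachable angle range
    (or above 180°) are clipped to it; with the receptor presets this
    affects only the far upper tail.
    """
    base = build_ideal_helix(helix)
    vertex_res = helix.residue_start + helix.n_res // 2
    geom = _kink_geometry(base, vertex_res)
    angle_floor = float(
        _angles_at_rotation(geom, np.array([geom.phi_max + math.pi / 2]))[0]
    )
    angle_ceil = float(_angles_at_rotation(geom, np.array([geom.phi_max]))[0])
    lo = angle_floor + 1e-3
    hi = min(angle_ceil, 180.0) - 1e-3

    trajectories = []
    for r, targets in enumerate(ar1_angle_series(kink, ens)):
        targets = np.clip(targets, lo, hi)
        phis = _solve_rotations(geom, targets)
        d = base.coords[geom.downstream] - geom.origin  # (m, 3), shared
        k = geom.axis
        cos_p = np.cos(phis)[:, None, None]
        sin_p = np.sin(phis)[:, None, None]
        cross = np.cross(k, d)[None, :, :]
        along = np.outer(d @ k, k)[None, :, :]
        rotated = cos_p * d[None, :, :] + sin_p * cross + (1 - cos_p) * along
        n_frames = len(targets)
        coords = np.broadcast_to(base.coords, (n_frames, len(base), 3)).copy()
        coords[:, geom.downstream, :] = geom.origin + rotated
        frames = [
            base.with_coords(coords[t], time_ps=t * ens.frame_interval_ps)
            for t in range(n_frames)
        ]
        trajectories.append(
            Trajectory(frames, replica_id=r + 1, frame_interval_ps=ens.frame_interval_ps)
        )
    return trajectories


def subsample_frames(
    trajectories: list[Trajectory], interval_ns: float
) -> tuple[list[Frame], int]:
    """One frame per ``interval_ns`` across replicas.

    The first replica contributes its frames at t = 0, Δ, 2Δ, ...
    (start inclusive); continuation replicas contribute t = Δ, 2Δ, ...
    (start exclusive, since their t = 0 duplicates the branch point of
    the parent run). The count therefore equals
    Σ_i floor(T_i / Δ) + 1 — e.g. 126 poses for the default
    [500, 250, 250, 250] ns ensemble at Δ = 10 ns.
    """
    if not trajectories:
        raise ValueError("no trajectories to subsample")
    interval_ps = interval_ns * 1000.0
    out: list[Frame] = []
    for i, traj in enumerate(trajectories):
        step = interval_ps / traj.frame_interval_ps
        if abs(step - round(step)) > 1e-9:
            raise ValueError(
                f"subsample interval {interval_ns} ns is not a multiple of the "
                f"frame interval {traj.frame_interval_ps} ps"
            )
        step = int(round(step))
        start = 0 if i == 0 else step
        out.extend(traj.frames[start::step])
    return out, len(out)


# ---------------------------------------------------------------------------
# Toy 7-helix bundle
# ---------------------------------------------------------------------------

def build_toy_bundle(
    n_helices: int = 7,
    ring_radius: float = 7.5,
    helix_spec: HelixSpec | None = None,
    channel_seed_point: np.ndarray | None = None,
    min_clearance: float = 1.0,
) -> tuple[Frame, np.ndarray]:
    """Parallel helices on a circle enclosing a central channel.

    Returns the bundle frame and the channel seed point (bundle center at
    mid-height unless given). The default ring radius of 7.5 Å places the
    channel wall ~5.2 Å from the axis, inside the default cavity
    distance band, while inter-helix gaps stay too narrow to leak.
    Raises :class:`StructureError` if helices clash (< ``min_clearance``
    Å between atoms of different helices) or if the seed point lies
    within 2 Å of an atom.
    """
    spec = helix_spec if helix_spec is not None else HelixSpec(n_res=30)
    names, res_idx, res_names, chains, coords = [], [], [], [], []
    for k in range(n_helices):
        ang = 2 * math.pi * k / n_helices
        offset = np.array([ring_radius * math.cos(ang), ring_radius * math.sin(ang), 0.0])
        helix = build_ideal_helix(replace(spec, chain=chr(ord("A") + k)))
        names.extend(helix.names)
        res_idx.extend(helix.residue_indices)
        res_names.extend(helix.residue_names)
        chains.extend(helix.chains)
        coords.append(helix.coords + offset)
    frame = Frame(
        np.array(names, dtype=object),
        np.array(res_idx, dtype=int),
        np.array(res_names, dtype=object),
        np.array(chains, dtype=object),
        np.concatenate(coords),
    )

    from scipy.spatial import cKDTree

    chains_arr = frame.chains
    tree = cKDTree(frame.coords)
    pairs = tree.query_pairs(r=min_clearance, output_type="ndarray")
    for i, j in pairs:
        if chains_arr[i] != chains_arr[j]:
            raise StructureError(
                f"ring radius {ring_radius} Å too small: helices "
                f"{chains_arr[i]}/{chains_arr[j]} clash"
            )

    if channel_seed_point is None:
        z_mid = 0.5 * (frame.coords[:, 2].min() + frame.coords[:, 2].max())
        seed = np.array([0.0, 0.0, z_mid])
    else:
        seed = np.asarray(channel_seed_point, dtype=float)
    nearest, _ = tree.query(seed)
    if nearest < 2.0:
        raise StructureError(f"channel seed point within 2 Å of an atom ({nearest:.2f} Å)")
    return frame, seed


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSpec:
    """Saturation-binding generator settings (concentrations in molar)."""

    pKd: float
    amplitude: float = 0.3
    baseline: float = 0.1
    hill: float = 1.0
    noise_sd: float = 0.015
    concentrations: tuple[float, ...] = ()
    n_replicates: int = 2
    n_controls: int = 4
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.concentrations:
            # 10 concentrations spanning pKd ± 2 log units
            conc = np.logspace(-self.pKd - 2.0, -self.pKd + 2.0, 10)
            object.__setattr__(self, "concentrations", tuple(conc))
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


#: Receptor binding presets: BODIPY-cyclopamine pKd per construct.
BINDING_PRESETS: dict[str, float] = {
    "smo_wt": 6.87,
    "smo_F643P": 5.44,
    "fzd6_wt": 6.45,
    "fzd6_P643F": 6.28,
}


def binding_preset(name: str, seed: int = 0, **overrides) -> BindingSpec:
    """A :class:`BindingSpec` for a receptor construct: preset pKd, noise
    SD of 5% of the amplitude, 10 concentrations spanning pKd ± 2 log
    units, duplicate wells."""
    if name not in BINDING_PRESETS:
        raise KeyError(f"unknown binding preset {name!r}; options: {sorted(BINDING_PRESETS)}")
    kwargs = dict(pKd=BINDING_PRESETS[name], seed=seed, condition=name)
    kwargs.update(overrides)
    spec = BindingSpec(**kwargs)
    if "noise_sd" not in overrides:
        spec = replace(spec, noise_sd=0.05 * spec.amplitude)
    return spec


def _saturation_response(conc: np.ndarray, spec: BindingSpec) -> np.ndarray:
    kd = 10.0 ** (-spec.pKd)
    c_h = conc ** spec.hill
    return spec.baseline + spec.amplitude * c_h / (kd ** spec.hill + c_h)


def generate_binding_table(spec: BindingSpec) -> pd.DataFrame:
    """Tidy saturation-binding table with homoscedastic Normal noise.

    Columns: sample_id, condition, concentration_M, replicate, response,
    is_control. Control rows emulate acceptor-free wells (response ≈
    baseline + noise, no concentration).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sample = 0
    for rep in range(1, spec.n_replicates + 1):
        for conc in spec.concentrations:
            y = _saturation_response(np.array(conc), spec)
            rows.append((f"w{sample:03d}", spec.condition, conc, rep,
                         float(y + rng.normal(0.0, spec.noise_sd)), False))
            sample += 1
    for i in range(spec.n_controls):
        rows.append((f"c{i:03d}", spec.condition, np.nan, 1,
                     float(spec.baseline + rng.normal(0.0, spec.noise_sd)), True))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "concentration_M", "replicate",
                 "response", "is_control"],
    )


def generate_dose_response(
    kind: str, params: dict, seed: int = 0
) -> pd.DataFrame:
    """Noisy dose-response / titration tables.

    * ``"bell"``: biphasic rise-then-fall over log10 molar concentration
      (params: p0, p1, p2, m1, m2, h1, h2, concentrations, noise_sd,
      n_replicates) — the SAG1.3-style recruitment shape;
    * ``"one_phase"``: y = Y0 + (plateau - Y0)(1 - exp(-K x)) over an
      acceptor dose (params: y0, plateau, k, doses, ...);
    * ``"linear"``: y = intercept + slope * x.
    """
    from .binding_models import bell_response

    rng = np.random.default_rng(seed)
    noise_sd = params.get("noise_sd", 0.0)
    n_rep = params.get("n_replicates", 1)
    rows = []
    if kind == "bell":
        conc = np.asarray(params["concentrations"], dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        logc = np.log10(conc)
        mean = bell_response(
            logc, params["p0"], params["p1"], params["p2"],
            params["m1"], params["m2"], params.get("h1", 1.0), params.get("h2", 1.0),
        )
        x, xcol = conc, "concentration_M"
    elif kind == "one_phase":
        x = np.asarray(params["doses"], dtype=float)
        mean = params["y0"] + (params["plateau"] - params["y0"]) * (
            1.0 - np.exp(-params["k"] * x)
        )
        xcol = "acceptor_dose"
    elif kind == "linear":
        x = np.asarray(params["doses"], dtype=float)
        mean = params["intercept"] + params["slope"] * x
        xcol = "acceptor_dose"
    else:
        raise ValueError(f"unknown dose-response kind {kind!r}")

    sample = 0
    for rep in range(1, n_rep + 1):
        noisy = mean + rng.normal(0.0, noise_sd, size=mean.shape)
        for xi, yi in zip(x, noisy):
            rows.append((f"w{sample:03d}", kind, float(xi), rep, float(yi), False))
            sample += 1
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", xcol, "replicate", "response", "is_control"]
    )
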