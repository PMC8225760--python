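"""Per-frame TM6 kink-angle statistics.

The kink metric is the interior angle at the backbone nitrogen of the
vertex residue (BW 6.43 by default) between rays to the backbone
nitrogens four residues up- and downstream (6.39 and 6.47): a straight
helix scores close to 180°, a kinked one lower. Raw per-frame series
are optionally smoothed with a centered moving average for display;
summary statistics are always computed on the raw angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bw_numbering import ResidueMap
from .structure_io import AtomSelectionError, Frame, Trajectory

__all__ = [
    "KinkAngleSeries",
    "AngleSummary",
    "three_point_angle",
    "three_point_angles",
    "tm6_kink_series",
    "moving_average",
    "summarize_angles",
]


def three_point_angles(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Vectorized interior angle (degrees, [0, 180]) at vertex ``p2``.

    Inputs are broadcastable (..., 3) arrays.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("angle undefined: a flank point coincides with the vertex")
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def three_point_angle(p1, p2, p3) -> float:
    """Interior angle at vertex ``p2`` between rays to ``p1`` and ``p3``."""
    return float(three_point_angles(p1, p2, p3))


@dataclass
class KinkAngleSeries:
    """Per-frame kink angles of one replica, with optional smoothed trace."""

    replica_id: int
    times_ns: np.ndarray
    angles_deg: np.ndarray
    smoothed_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.times_ns.shape != self.angles_deg.shape:
            raise ValueError("times and angles must have equal length")
        if np.any(self.angles_deg <= 0) or np.any(self.angles_deg > 180):
            raise ValueError("angles must lie in (0, 180] degrees")
        if self.smoothed_deg is not None:
            self.smoothed_deg = np.asarray(self.smoothed_deg, dtype=float)
            if self.smoothed_deg.shape != self.angles_deg.shape:
                raise ValueError("smoothed trace must match raw length")

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass
class AngleSummary:
    """Frame-pooled mean ± SD over replicas, plus per-replica means."""

    mean_deg: float
    sd_deg: float
    n_frames: int
    replica_means: dict[int, float]
    single_frame: bool = False


def _bw_neighbor(bw_code: str, offset: int) -> str:
    helix, num = bw_code.split(".")
    return f"{helix}.{int(num) + offset}"


def tm6_kink_series(
    traj: Trajectory,
    resmap: ResidueMap,
    vertex_bw: str = "6.43",
    atom_name: str = "N",
) -> KinkAngleSeries:
    """Per-frame three-point angle at the backbone N of ``vertex_bw``
    between the backbone N atoms 4 residues before and after (e.g.
    6.39/6.43/6.47)."""
    codes = [_bw_neighbor(vertex_bw, -4), vertex_bw, _bw_neighbor(vertex_bw, +4)]
    residues = [resmap.residue(c) for c in codes]

    f0 = traj.frames[0]
    idx = []
    for code, res in zip(codes, residues):
        hits = np.flatnonzero((f0.residue_indices == res) & (f0.names == atom_name))
        if len(hits) != 1:
            raise AtomSelectionError(
                f"frame 0: expected one {atom_name!r} atom for BW {code} "
                f"(residue {res}), found {len(hits)}"
            )
        idx.append(int(hits[0]))

    coords = np.stack([f.coords for f in traj.frames])  # (n_frames, n_atoms, 3)
    angles = three_point_angles(coords[:, idx[0]], coords[:, idx[1]], coords[:, idx[2]])
    times_ns = traj.times_ps / 1000.0
    return KinkAngleSeries(traj.replica_id, times_ns, angles)


def _box_smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centered boxcar mean with truncated edges; length preserved."""
    h = (w - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_average(series: KinkAngleSeries, window_ns: float = 1.0) -> KinkAngleSeries:
    """Return the series with a centered moving-average trace attached.

    The window is ``round(window_ns / frame interval)`` frames, forced odd
    (+1 if even); edge frames average over the truncated available window
    so the series length is preserved.
    """
    if len(series) > 1:
        interval = float(series.times_ns[1] - series.times_ns[0])
    else:
        interval = window_ns
    if window_ns < interval - 1e-12:
        raise ValueError(
            f"smoothing window {window_ns} ns is smaller than the frame interval {interval} ns"
        )
    w = int(round(window_ns / interval))
    if w % 2 == 0:
        w += 1
    smoothed = _box_smooth(series.angles_deg, w)
    return KinkAngleSeries(series.replica_id, series.times_ns, series.angles_deg, smoothed)


def summarize_angles(series_list: list[KinkAngleSeries]) -> AngleSummary:
    """Frame-pooled mean ± SD (ddof=1) over the raw angles of all replicas.

    Pooling is frame-weighted: longer replicas contribute proportionally
    more frames. Per-replica means are reported alongside.
    """
    if not series_list:
        raise ValueError("summarize_angles requires at least one series")
    pooled = np.concatenate([s.angles_deg for s in series_list])
    n = len(pooled)
    sd = float(np.std(pooled, ddof=1)) if n > 1 else 0.0
    return AngleSummary(
        mean_deg=float(np.mean(pooled)),
        sd_deg=sd,
        n_frames=n,
        replica_means={s.replica_id: float(np.mean(s.angles_deg)) for s in series_list},
        single_frame=(n == 1),
    )
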