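"""Collective residue motion: velocity fields and spatial correlation C(r).

Consecutive frames t and t+1 are superposed (all-atom Kabsch fit, proper
rotation only) to remove whole-molecule translation and rotation; the residual
residue-center displacements divided by the saving interval give per-residue
velocities u_i.  The spatial correlation

    C(r) = < u_i . u_j / (|u_i| |u_j|) >   over pairs at mutual distance r

is accumulated in distance bins; the correlation length xi is the first
zero crossing of C(r), and rescaling the abscissa to x = r/xi exposes the
scale-free shape of the curve.

Normalisation happens per frame (cosine similarity) by default; the
alternative of dividing the binned mean dot product by the global mean squared
speed is available as ``normalize="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .io import Frame, Trajectory, residue_centers

__all__ = [
    "RigidTransform",
    "VelocityField",
    "CorrelationCurve",
    "kabsch_align",
    "residue_velocities",
    "correlation_function",
    "correlation_length",
    "rescale_curve",
]


@dataclass
class RigidTransform:
    """Proper rigid-body map x -> R x + t."""

    rotation: np.ndarray     # (3, 3), orthogonal, det +1
    translation: np.ndarray  # (3,), nm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-10:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class VelocityField:
    """Per-residue velocities (nm/ps) after rigid-body removal."""

    velocities: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")


@dataclass
class CorrelationCurve:
    """Distance-binned normalized velocity correlation."""

    r_centers: np.ndarray   # nm, increasing; only occupied bins kept
    C: np.ndarray
    pair_counts: np.ndarray
    xi: float | None = None
    n_skipped_pairs: int = 0

    def __post_init__(self) -> None:
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.r_centers) <= 0):
            raise ValueError("r_centers must be strictly increasing")


def kabsch_align(mobile: Frame, reference: Frame
                 ) -> tuple[RigidTransform, Frame, float]:
    """Least-RMSD superposition of ``mobile`` onto ``reference`` (all atoms).

    Returns the minimizing proper rigid transform, the transformed frame and
    the residual RMSD (nm).  Degenerate point sets (collinear/coincident)
    still return a minimizing proper rotation.
    """
    if mobile.n_atoms != reference.n_atoms or not np.array_equal(
        mobile.residue_indices, reference.residue_indices
    ):
        raise ValueError("frames must share an identical atom structure")
    mob = mobile.coordinates
    ref = reference.coordinates
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    transform = RigidTransform(rotation=R, translation=t)
    aligned = mobile.transformed(R, t)
    rmsd = float(np.sqrt(np.mean(
        np.sum((aligned.coordinates - ref) ** 2, axis=1))))
    return transform, aligned, rmsd


def residue_velocities(traj: Trajectory, t: int) -> VelocityField:
    """u_i = (aligned residue-center_i(t+1) - residue-center_i(t)) / dt."""
    if not 0 <= t < traj.n_frames - 1:
        raise ValueError(f"frame index t={t} out of range [0, {traj.n_frames - 1})")
    _, aligned, _ = kabsch_align(traj.frames[t + 1], traj.frames[t])
    v = (residue_centers(aligned) - residue_centers(traj.frames[t])) / traj.dt
    return VelocityField(velocities=v, frame_index=t)


def correlation_function(traj: Trajectory, bin_width: float = 0.1,
                         normalize: str = "per_frame") -> CorrelationCurve:
    """Distance-binned velocity correlation over all consecutive frame pairs.

    For every frame pair (t, t+1) and residue pair i < j the normalized
    correlation cos(theta_ij) is accumulated in the bin of the residue-center
    distance r_ij measured at frame t.  Zero-magnitude velocities are skipped
    and counted.  ``normalize="global"`` divides the binned mean dot product
    by the global mean squared speed instead.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if normalize not in ("per_frame", "global"):
        raise ValueError("normalize must be 'per_frame' or 'global'")

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    skipped = 0
    any_motion = False
    sq_speed_sum = 0.0
    sq_speed_n = 0
    # below this speed a residue is numerically at rest (Kabsch rounding noise)
    eps = 1e-13
    for t in range(traj.n_frames - 1):
        u = residue_velocities(traj, t).velocities
        mags = np.linalg.norm(u, axis=1)
        mags = np.where(mags < eps, 0.0, mags)
        if np.all(mags == 0):
            continue
        any_motion = True
        centers = residue_centers(traj.frames[t])
        n = len(centers)
        iu, ju = np.triu_indices(n, k=1)
        r = pdist(centers)
        dots = np.einsum("ij,ij->i", u[iu], u[ju])
        denom = mags[iu] * mags[ju]
        ok = denom > 0
        skipped += int(np.count_nonzero(~ok))
        sq_speed_sum += float(np.sum(mags ** 2))
        sq_speed_n += n
        if normalize == "per_frame":
            contrib = dots[ok] / denom[ok]
        else:
            contrib = dots[ok]
        bins = np.floor(r[ok] / bin_width).astype(int)
        for b, c in zip(bins.tolist(), contrib.tolist()):
            sums[b] = sums.get(b, 0.0) + c
            counts[b] = counts.get(b, 0) + 1
    if not any_motion:
        raise ValueError(
            "all velocity fields are zero; consider a larger frame interval dt"
        )
    occupied = sorted(counts)
    r_centers = np.array([(b + 0.5) * bin_width for b in occupied])
    C = np.array([sums[b] / counts[b] for b in occupied])
    if normalize == "global":
        C = C / (sq_speed_sum / sq_speed_n)
    pair_counts = np.array([counts[b] for b in occupied])
    curve = CorrelationCurve(r_centers=r_centers, C=C, pair_counts=pair_counts,
                             n_skipped_pairs=skipped)
    curve.xi = correlation_length(curve)
    return curve


def correlation_length(curve: CorrelationCurve) -> float | None:
    """First positive-to-non-positive zero crossing of C(r), by linear
    interpolation between the bracketing bins; None when no crossing exists."""
    C = curve.C
    r = curve.r_centers
    started = False
    for k in range(len(C)):
        if C[k] > 0:
            started = True
        elif started:
            r0, r1 = r[k - 1], r[k]
            c0, c1 = C[k - 1], C[k]
            if c1 == c0:
                return float(r1)
            return float(r0 + (r1 - r0) * c0 / (c0 - c1))
    return None


def rescale_curve(curve: CorrelationCurve,
                  xi: float | None = None) -> CorrelationCurve:
    """Map the abscissa to x = r/xi; the rescaled curve crosses zero at x=1."""
    xi = curve.xi if xi is None else xi
    if xi is None or xi <= 0:
        raise ValueError("correlation length xi is required for rescaling")
    return CorrelationCurve(
        r_centers=curve.r_centers / xi,
        C=curve.C.copy(),
        pair_counts=curve.pair_counts.copy(),
        xi=1.0,
        n_skipped_pairs=curve.n_skipped_pairs,
    )
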