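"""Trajectory and time-series containers plus text-format readers/writers.

Coordinates are stored in nanometres throughout the package.  PDB files carry
Angstroms, so values are divided by 10 on read and multiplied by 10 on write.
XYZ files are this package's own coarse-grained dialect and are interpreted
directly as nanometres (one bead per residue).

Frame times are never inferred from files: neither format carries a reliable
clock, so ``dt`` is a caller option defaulting to 100 ps, the coordinate
saving interval used for the all-atom trajectories this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "TimeSeries",
    "ParseError",
    "StructuralError",
    "read_multiframe_pdb",
    "write_multiframe_pdb",
    "read_xyz",
    "write_xyz",
    "read_timeseries",
    "write_timeseries",
    "residue_centers",
    "end_to_end_series",
    "radius_of_gyration",
]

DEFAULT_DT_PS = 100.0

# Masses (amu) for elements commonly present in protein PDB files; anything
# else (or a missing element column) falls back to 1.0, i.e. geometric center.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845,
    "ZN": 65.38, "MG": 24.305, "NA": 22.990, "CL": 35.45, "K": 39.098,
}


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class StructuralError(ValueError):
    """Frames of a trajectory file disagree in atom content."""


class Atom(NamedTuple):
    residue_index: int
    coordinates: np.ndarray  # shape (3,), nm
    mass: float = 1.0


@dataclass
class Frame:
    """One conformation: atom coordinates grouped into contiguous residues.

    Stored as flat arrays for speed; ``atoms`` offers the per-atom view.
    """

    coordinates: np.ndarray          # (n_atoms, 3), nm
    residue_indices: np.ndarray      # (n_atoms,), int, 0-based contiguous
    masses: np.ndarray | None = None  # (n_atoms,), amu; None -> unit masses

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if len(self.residue_indices) != len(self.coordinates):
            raise ValueError("residue_indices length must match coordinates")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.ones(len(self.coordinates))
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != len(self.coordinates):
                raise ValueError("masses length must match coordinates")
            if np.any(self.masses <= 0):
                raise ValueError("masses must be positive")
        uniq = np.unique(self.residue_indices)
        n = self.residue_count
        if not (uniq.size == n and uniq[0] == 0 and uniq[-1] == n - 1):
            raise ValueError(
                "residue indices must form a contiguous range 0..N-1"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def residue_count(self) -> int:
        return int(self.residue_indices.max()) + 1 if self.n_atoms else 0

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(int(r), c, float(m))
            for r, c, m in zip(self.residue_indices, self.coordinates, self.masses)
        ]

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom]) -> "Frame":
        return cls(
            coordinates=np.array([a.coordinates for a in atoms], dtype=float),
            residue_indices=np.array([a.residue_index for a in atoms]),
            masses=np.array([a.mass for a in atoms], dtype=float),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Return a copy with coordinates mapped to R @ x + t."""
        return Frame(
            coordinates=self.coordinates @ np.asarray(rotation).T
            + np.asarray(translation),
            residue_indices=self.residue_indices.copy(),
            masses=self.masses.copy(),
        )


@dataclass
class Trajectory:
    """Ordered frames with a fixed inter-frame interval ``dt`` (ps)."""

    frames: list[Frame]
    dt: float = DEFAULT_DT_PS

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames[1:], start=1):
            if fr.n_atoms != ref.n_atoms or not np.array_equal(
                fr.residue_indices, ref.residue_indices
            ):
                raise StructuralError(
                    f"frame {k} does not share the atom/residue structure of frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].residue_count


@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal with sampling interval ``dt``."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("time series must be 1-D with length >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int):
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ParseError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    chain = line[21:22]
    resseq = line[22:26].strip()
    icode = line[26:27]
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    mass = ELEMENT_MASSES.get(element, 1.0)
    # lengths nm internally; PDB carries Angstrom
    return (chain, resseq, icode), np.array([x, y, z]) / 10.0, mass


def read_multiframe_pdb(path: str | Path, dt: float = DEFAULT_DT_PS) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`.

    Residue identity is (chain id, residue number, insertion code), renumbered
    0-based contiguously in order of first appearance.  All MODELs must carry
    the same atoms; a mismatch raises :class:`StructuralError` naming the
    offending MODEL.
    """
    path = Path(path)
    frames_raw: list[list] = []
    current: list | None = None
    model_ids: list[str] = []
    seen_any_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current is not None and current:
                    frames_raw.append(current)
                current = []
                model_ids.append(line[6:].strip() or str(len(model_ids) + 1))
            elif rec == "ENDMDL":
                if current is not None:
                    frames_raw.append(current)
                    current = None
            elif rec in ("ATOM", "HETATM"):
                seen_any_atom = True
                if current is None:
                    current = []
                    if not model_ids:
                        model_ids.append("1")
                current.append(_parse_pdb_atom(line, lineno))
    if current:
        frames_raw.append(current)
    if not frames_raw or not seen_any_atom:
        raise ParseError(f"no coordinate records found in {path}")

    n0 = len(frames_raw[0])
    for k, fr in enumerate(frames_raw):
        if len(fr) != n0:
            mid = model_ids[k] if k < len(model_ids) else str(k + 1)
            raise StructuralError(
                f"MODEL {mid} has {len(fr)} atoms, expected {n0}"
            )

    # residue renumbering from the first frame's order of first appearance
    order: dict = {}
    for key, _, _ in frames_raw[0]:
        if key not in order:
            order[key] = len(order)

    frames = []
    for fr in frames_raw:
        coords = np.array([c for _, c, _ in fr])
        masses = np.array([m for _, _, m in fr])
        try:
            resi = np.array([order[key] for key, _, _ in fr])
        except KeyError as exc:
            raise StructuralError(
                f"residue {exc} appears in a later MODEL but not in the first"
            ) from exc
        frames.append(Frame(coords, resi, masses))
    return Trajectory(frames, dt=dt)


_MASS_TO_ELEMENT = {round(m, 3): e for e, m in ELEMENT_MASSES.items() if len(e) <= 2}


def write_multiframe_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB (coordinates nm -> Angstrom)."""
    path = Path(path)
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for resi, xyz, mass in zip(
                frame.residue_indices, frame.coordinates, frame.masses
            ):
                element = _MASS_TO_ELEMENT.get(round(float(mass), 3), "C")
                x, y, z = xyz * 10.0
                fh.write(
                    f"ATOM  {serial % 100000:5d} {element:<4s}"
                    f"{'GLY':>3s} A{(int(resi) + 1) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ (package dialect: coordinates in nm, one bead per residue)
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, dt: float = DEFAULT_DT_PS) -> Trajectory:
    """Read an XYZ trajectory; every bead becomes a one-atom residue.

    Coordinates are taken as nanometres — this dialect is used only for the
    package's own coarse-grained chains.
    """
    path = Path(path)
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"empty XYZ file: {path}")
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_index}: bad atom-count line {pos + 1!r}"
            ) from exc
        body = lines[pos + 2: pos + 2 + count]
        if len(body) < count:
            raise ParseError(
                f"frame {frame_index}: expected {count} coordinate lines, "
                f"found {len(body)}"
            )
        coords = np.empty((count, 3))
        for i, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(
                    f"frame {frame_index}: malformed coordinate line {ln!r}"
                )
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(
                    f"frame {frame_index}: malformed coordinate line {ln!r}"
                ) from exc
        frames.append(Frame(coords, np.arange(count)))
        pos += 2 + count
        frame_index += 1
    return Trajectory(frames, dt=dt)


def write_xyz(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    """Write one bead per residue (residue centers) in nm, full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        for frame in traj.frames:
            centers = residue_centers(frame)
            fh.write(f"{len(centers)}\n{comment}\n")
            for c in centers:
                fh.write(f"CG {c[0]:.9f} {c[1]:.9f} {c[2]:.9f}\n")


# ---------------------------------------------------------------------------
# TimeSeries TSV
# ---------------------------------------------------------------------------

def write_timeseries(ts: TimeSeries, path: str | Path,
                     header: str = "time_ps\tvalue_nm") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for t, v in zip(ts.times, ts.values):
            fh.write(f"{t:.9g}\t{v:.12g}\n")


def read_timeseries(path: str | Path) -> TimeSeries:
    data = np.loadtxt(path, skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ParseError(f"time-series file {path} must have >=2 rows, 2 columns")
    t, v = data[:, 0], data[:, 1]
    dts = np.diff(t)
    if np.any(dts <= 0) or np.ptp(dts) > 0.01 * dts.mean():
        raise ParseError("time column must be uniformly increasing")
    return TimeSeries(values=v, dt=float(dts.mean()))


# ---------------------------------------------------------------------------
# Residue-level observables
# ---------------------------------------------------------------------------

def residue_centers(frame: Frame) -> np.ndarray:
    """Mass-weighted centers of mass per residue, shape (N, 3)."""
    n = frame.residue_count
    w = frame.masses
    tot = np.bincount(frame.residue_indices, weights=w, minlength=n)
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = np.bincount(
            frame.residue_indices, weights=w * frame.coordinates[:, ax], minlength=n
        )
    return out / tot[:, None]


def end_to_end_series(traj: Trajectory, i: int | None = None,
                      j: int | None = None) -> TimeSeries:
    """Per-frame COM distance between residues i and j (defaults: termini)."""
    n = traj.n_residues
    if i is None:
        i = 0
    if j is None:
        j = n - 1
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"residue indices must be in [0, {n}); got {i}, {j}")
    if i == j:
        raise ValueError("residue indices i and j must differ")
    vals = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        centers = residue_centers(frame)
        vals[k] = np.linalg.norm(centers[i] - centers[j])
    return TimeSeries(values=vals, dt=traj.dt)


def radius_of_gyration(points: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """sqrt(sum m |r - rbar|^2 / sum m); unit masses by default."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("radius_of_gyration requires at least one point")
    points = points.reshape(-1, 3)
    if masses is None:
        masses = np.ones(len(points))
    else:
        masses = np.asarray(masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")
    com = np.average(points, axis=0, weights=masses)
    sq = np.sum((points - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))
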