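"""Synthetic inputs: HP heteropolymer Langevin dynamics, colored noise,
planted-domain conformers, power-law sizes, Gaussian chains, hinge motions.

The heteropolymer control emulates a near-theta-point chain of hydrophobic
(H) and polar (P) beads, one bead per residue: harmonic bonds plus an
Ashbaugh–Hatch lambda-scaled Lennard-Jones non-bonded potential (full LJ
shifted up by (1-lambda) eps inside the minimum, lambda-scaled attractive
tail outside; purely repulsive at lambda = 0).  Defaults are HPS-flavoured
reduced-ish units: lengths in nm, energies in kJ/mol, time in ps, unit bead
mass — the published coarse-grained parameter set is not public, so the
simulator is parameterized rather than calibrated and downstream checks on
its output are qualitative.

Every generator is deterministic under (seed, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Frame, TimeSeries, Trajectory

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "HPSequence",
    "HPModelParams",
    "PlantedConformerSpec",
    "generate_hp_sequences",
    "simulate_hp_polymer",
    "quench_hp_polymer",
    "hp_potential_energy",
    "colored_noise",
    "planted_domain_frame",
    "power_law_sizes",
    "gaussian_chain",
    "hinge_motion_pair",
    "write_hp_sequences",
    "read_hp_sequences",
]

KB_KJ_PER_MOL_K = 0.00831446


@dataclass
class HPSequence:
    """Two-letter (H/P) heteropolymer sequence."""

    beads: str

    def __post_init__(self) -> None:
        self.beads = "".join(self.beads).upper()
        if len(self.beads) < 2:
            raise ValueError("sequence length must be >= 2")
        if set(self.beads) - {"H", "P"}:
            raise ValueError("beads must be 'H' or 'P'")

    @property
    def length(self) -> int:
        return len(self.beads)

    @property
    def n_hydrophobic(self) -> int:
        return self.beads.count("H")

    def lambdas(self, lambda_H: float, lambda_P: float) -> np.ndarray:
        return np.array(
            [lambda_H if b == "H" else lambda_P for b in self.beads]
        )


@dataclass
class HPModelParams:
    """Coarse-grained chain parameters (nm, kJ/mol, ps, amu)."""

    bond_k: float = 500.0      # kJ/mol/nm^2
    bond_b: float = 0.38       # nm
    lj_sigma: float = 0.45     # nm
    lj_epsilon: float = 1.0    # kJ/mol
    lambda_H: float = 1.0
    lambda_P: float = 0.0
    temperature: float = 300.0  # K
    friction: float = 0.5      # 1/ps; ~critical damping of the slowest mode
    timestep: float = 0.002    # ps; resolves LJ collisions at unit bead mass
    mass: float = 1.0          # amu per bead
    cutoff_factor: float = 3.0  # non-bonded cutoff in units of sigma

    def __post_init__(self) -> None:
        positives = dict(bond_k=self.bond_k, bond_b=self.bond_b,
                         lj_sigma=self.lj_sigma, lj_epsilon=self.lj_epsilon,
                         friction=self.friction, timestep=self.timestep,
                         mass=self.mass, cutoff_factor=self.cutoff_factor)
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        for name, lam in (("lambda_H", self.lambda_H),
                          ("lambda_P", self.lambda_P)):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def kT(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature


@dataclass
class PlantedConformerSpec:
    """Ground-truth conformer: compact residue clusters + extended linker."""

    N: int
    cluster_assignments: list          # of set/frozenset of residue indices
    cluster_spacing: float = 3.0       # nm between cluster centers
    intra_cluster_scale: float = 0.3   # nm, max intra-cluster extent
    contact_cutoff: float = 0.35       # nm, cutoff the construction targets

    def __post_init__(self) -> None:
        self.cluster_assignments = [frozenset(c) for c in self.cluster_assignments]
        seen: set = set()
        for c in self.cluster_assignments:
            if seen & c:
                raise ValueError("clusters must be disjoint")
            if any(not 0 <= i < self.N for i in c):
                raise ValueError("cluster residue index out of range")
            seen |= c
        if self.cluster_spacing <= 2 * self.contact_cutoff:
            raise ValueError("cluster_spacing must exceed 2x the contact cutoff")


def generate_hp_sequences(L: int, frac_H: float = 0.5, n: int = 100,
                          seed: int = 0) -> list[HPSequence]:
    """Random H/P sequences with exactly floor(frac_H * L) H beads each."""
    if L < 2:
        raise ValueError("L must be >= 2")
    if not 0.0 <= frac_H <= 1.0:
        raise ValueError("frac_H must lie in [0, 1]")
    n_h = int(frac_H * L)  # floor rule: 36 H beads at L=73, frac 0.5
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n):
        beads = np.full(L, "P")
        beads[rng.choice(L, size=n_h, replace=False)] = "H"
        seqs.append(HPSequence("".join(beads)))
    return seqs


# ---------------------------------------------------------------------------
# HP chain energetics + BAOAB Langevin integrator (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hp_forces(x, lam, bond_k, bond_b, sigma, eps, rc2, f):
    n = x.shape[0]
    for i in range(n):
        for d in range(3):
            f[i, d] = 0.0
    pe = 0.0
    sig2 = sigma * sigma
    rmin2 = sig2 * 2.0 ** (1.0 / 3.0)
    # bonds
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_b
        pe += 0.5 * bond_k * dr * dr
        if r > 1e-12:
            fmag = -bond_k * dr / r
            f[i + 1, 0] += fmag * dx
            f[i + 1, 1] += fmag * dy
            f[i + 1, 2] += fmag * dz
            f[i, 0] -= fmag * dx
            f[i, 1] -= fmag * dy
            f[i, 2] -= fmag * dz
    # non-bonded (|i - j| >= 2), Ashbaugh-Hatch lambda-scaled LJ
    for i in range(n):
        for j in range(i + 2, n):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2 or r2 < 1e-12:
                continue
            lam_ij = 0.5 * (lam[i] + lam[j])
            inv2 = sig2 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            ulj = 4.0 * eps * (inv12 - inv6)
            # force magnitude / r  (positive = repulsive)
            fr = 24.0 * eps * (2.0 * inv12 - inv6) / r2
            if r2 < rmin2:
                pe += ulj + (1.0 - lam_ij) * eps
            else:
                pe += lam_ij * ulj
                fr *= lam_ij
            f[j, 0] += fr * dx
            f[j, 1] += fr * dy
            f[j, 2] += fr * dz
            f[i, 0] -= fr * dx
            f[i, 1] -= fr * dy
            f[i, 2] -= fr * dz
    return pe


@njit(cache=True)
def _hp_run(x0, lam, bond_k, bond_b, sigma, eps, rc2, mass, gamma, kT, dt,
            n_steps, save_every, seed):
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = np.zeros((n, 3))
    if kT > 0.0:
        v = np.random.standard_normal((n, 3)) * math.sqrt(kT / mass)
    f = np.zeros((n, 3))
    _hp_forces(x, lam, bond_k, bond_b, sigma, eps, rc2, f)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, (1.0 - c1 * c1)) * kT / mass)
    n_saved = n_steps // save_every
    out = np.empty((n_saved, n, 3))
    isave = 0
    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d] / mass
                x[i, d] += half * v[i, d]
        if c2 > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * noise[i, d]
        else:
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d]
        for i in range(n):
            for d in range(3):
                x[i, d] += half * v[i, d]
        _hp_forces(x, lam, bond_k, bond_b, sigma, eps, rc2, f)
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d] / mass
        if step % save_every == 0:
            if not np.all(np.isfinite(x)):
                return out[:isave], step
            out[isave] = x
            isave += 1
    return out, 0


def _initial_coords(L: int, b: float, rng: np.random.Generator) -> np.ndarray:
    """Slightly perturbed straight chain at bond spacing b."""
    x = np.zeros((L, 3))
    x[:, 0] = np.arange(L) * b
    x += rng.normal(scale=0.01 * b, size=(L, 3))
    return x


def hp_potential_energy(coords: np.ndarray, seq: HPSequence,
                        params: HPModelParams) -> float:
    """Total potential energy (kJ/mol) of a chain configuration."""
    lam = seq.lambdas(params.lambda_H, params.lambda_P)
    f = np.zeros_like(np.asarray(coords, dtype=float))
    rc2 = (params.cutoff_factor * params.lj_sigma) ** 2
    return float(_hp_forces(
        np.ascontiguousarray(coords, dtype=float), lam, params.bond_k,
        params.bond_b, params.lj_sigma, params.lj_epsilon, rc2, f,
    ))


def simulate_hp_polymer(seq: HPSequence, params: HPModelParams | None = None,
                        n_steps: int = 100_000, save_every: int = 100,
                        seed: int = 0,
                        initial_coords: np.ndarray | None = None) -> Trajectory:
    """Underdamped Langevin (BAOAB) trajectory of one HP chain.

    Frames are saved every ``save_every`` steps, so the trajectory's ``dt`` is
    ``save_every * params.timestep`` (ps).  A non-finite coordinate aborts
    with the failing step named.
    """
    if params is None:
        params = HPModelParams()
    if not n_steps >= save_every >= 1:
        raise ValueError("need n_steps >= save_every >= 1")
    rng = np.random.default_rng(seed)
    if initial_coords is None:
        x0 = _initial_coords(seq.length, params.bond_b, rng)
    else:
        x0 = np.array(initial_coords, dtype=float)
        if x0.shape != (seq.length, 3):
            raise ValueError("initial_coords must have shape (L, 3)")
    lam = seq.lambdas(params.lambda_H, params.lambda_P)
    rc2 = (params.cutoff_factor * params.lj_sigma) ** 2
    # numba's RNG takes a 32-bit-ish seed; derive one from the generator
    nb_seed = int(rng.integers(0, 2**31 - 1))
    out, blew_up_at = _hp_run(
        x0, lam, params.bond_k, params.bond_b, params.lj_sigma,
        params.lj_epsilon, rc2, params.mass, params.friction, params.kT,
        params.timestep, n_steps, save_every, nb_seed,
    )
    if blew_up_at:
        raise FloatingPointError(
            f"integrator blow-up: non-finite coordinates at step {blew_up_at}; "
            "try a smaller timestep"
        )
    frames = [Frame(c, np.arange(seq.length)) for c in out]
    return Trajectory(frames, dt=save_every * params.timestep)


def quench_hp_polymer(coords: np.ndarray, seq: HPSequence,
                      params: HPModelParams, n_steps: int = 100,
                      step_size: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Gradient descent with backtracking; potential energy never increases.

    Returns (final coordinates, per-step energies including the start).
    """
    x = np.array(coords, dtype=float)
    lam = seq.lambdas(params.lambda_H, params.lambda_P)
    rc2 = (params.cutoff_factor * params.lj_sigma) ** 2
    f = np.zeros_like(x)
    energies = [
        _hp_forces(x, lam, params.bond_k, params.bond_b, params.lj_sigma,
                   params.lj_epsilon, rc2, f)
    ]
    alpha = step_size
    for _ in range(n_steps):
        trial = x + alpha * f
        ftrial = np.zeros_like(x)
        e = _hp_forces(trial, lam, params.bond_k, params.bond_b,
                       params.lj_sigma, params.lj_epsilon, rc2, ftrial)
        while e > energies[-1] and alpha > 1e-12:
            alpha *= 0.5
            trial = x + alpha * f
            e = _hp_forces(trial, lam, params.bond_k, params.bond_b,
                           params.lj_sigma, params.lj_epsilon, rc2, ftrial)
        if e > energies[-1]:
            break
        x, f = trial, ftrial
        energies.append(e)
        alpha *= 1.1
    return x, np.array(energies)


# ---------------------------------------------------------------------------
# Colored noise by spectral synthesis
# ---------------------------------------------------------------------------

def colored_noise(beta: float, n: int, dt: float = 1.0,
                  seed: int = 0) -> TimeSeries:
    """Zero-mean, unit-variance signal with S(f) proportional to f^(-beta).

    Spectral synthesis: Fourier amplitudes f^(-beta/2), i.i.d. uniform random
    phases, Hermitian symmetry, inverse transform.
    """
    if not 0.0 <= beta <= 3.0:
        raise ValueError("beta must lie in [0, 3]")
    if n < 16:
        raise ValueError("n must be >= 16")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n // 2 + 1)
    freqs = k / (n * dt)
    amps = freqs ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(k))
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[1:] = amps * np.exp(1j * phases)
    if n % 2 == 0:  # Nyquist coefficient must be real
        spec[-1] = amps[-1] * (1.0 if rng.random() < 0.5 else -1.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    x /= x.std()
    return TimeSeries(values=x, dt=dt)


# ---------------------------------------------------------------------------
# Planted structures
# ---------------------------------------------------------------------------

def _ball_points(rng: np.random.Generator, n: int, radius: float,
                 center: np.ndarray) -> np.ndarray:
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return center + u * r[:, None]


def planted_domain_frame(spec: PlantedConformerSpec, seed: int = 0) -> Frame:
    """One-bead-per-residue frame with the specified compact clusters.

    Cluster members lie within ``intra_cluster_scale`` of each other so every
    non-sequence-adjacent member pair is in contact; non-cluster residues sit
    on a distant extended arc with all pairwise distances above the cutoff.
    The construction is validated before returning.
    """
    if spec.intra_cluster_scale >= spec.contact_cutoff:
        raise ValueError(
            "infeasible spec: intra_cluster_scale must be below the contact "
            "cutoff so cluster members are mutually in contact"
        )
    rng = np.random.default_rng(seed)
    coords = np.zeros((spec.N, 3))
    clustered: set = set()
    for m, cluster in enumerate(spec.cluster_assignments):
        members = sorted(cluster)
        center = np.array([m * spec.cluster_spacing, 0.0, 0.0])
        pts = _ball_points(rng, len(members), spec.intra_cluster_scale / 2.0,
                           center)
        for idx, p in zip(members, pts):
            coords[idx] = p
        clustered |= cluster
    linker = [i for i in range(spec.N) if i not in clustered]
    y0 = 10.0 + spec.cluster_spacing * max(1, len(spec.cluster_assignments))
    for k, idx in enumerate(linker):
        coords[idx] = [k * 2.0 * spec.contact_cutoff, y0, 0.0]
    frame = Frame(coords, np.arange(spec.N))
    _validate_planted(frame, spec)
    return frame


def _validate_planted(frame: Frame, spec: PlantedConformerSpec) -> None:
    from .domains import contact_graph  # local import to avoid cycles

    g = contact_graph(frame, cutoff=spec.contact_cutoff)
    membership = {}
    for m, cluster in enumerate(spec.cluster_assignments):
        for i in cluster:
            membership[i] = m
    within: dict[int, int] = {}
    for i, j in g.edges:
        mi, mj = membership.get(i), membership.get(j)
        if mi is None or mj is None or mi != mj:
            raise RuntimeError(
                f"planted construction produced a stray contact ({i}, {j})"
            )
        within[i] = within.get(i, 0) + 1
        within[j] = within.get(j, 0) + 1
    for cluster in spec.cluster_assignments:
        if len(cluster) >= 4:
            for i in cluster:
                if within.get(i, 0) < 2:
                    raise RuntimeError(
                        f"planted residue {i} has fewer than 2 in-cluster contacts"
                    )


def power_law_sizes(tau: float, s_min: int, s_max: int, n: int,
                    seed: int = 0) -> np.ndarray:
    """i.i.d. draws from the discrete distribution p(s) ~ s^(-tau) on
    [s_min, s_max] (inverse-CDF sampling)."""
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    support = np.arange(s_min, s_max + 1)
    w = support.astype(float) ** (-tau)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return support[np.searchsorted(cdf, u, side="left")]


def gaussian_chain(N: int, b: float = 0.38, seed: int = 0) -> Frame:
    """Ideal chain: i.i.d. isotropic Gaussian bonds with RMS length b."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if b <= 0:
        raise ValueError("b must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=b / np.sqrt(3.0), size=(N - 1, 3))
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Frame(coords, np.arange(N))


def hinge_motion_pair(N_block: int, separation: float = 4.0,
                      displacement: float = 0.2, seed: int = 0,
                      dt: float = 100.0,
                      block_radius: float | None = None) -> Trajectory:
    """Two mirror-symmetric compact blocks counter-translating along x.

    Frame 2 equals frame 1 with the blocks moved toward each other by
    ``displacement/2`` each; the displacement field has zero net translation
    and zero net angular momentum, so rigid-body alignment is neutral.
    """
    if block_radius is None:
        block_radius = separation / 4.0
    rng = np.random.default_rng(seed)
    a = _ball_points(rng, N_block, block_radius,
                     np.array([-separation / 2.0, 0.0, 0.0]))
    b = a * np.array([-1.0, 1.0, 1.0])  # mirror through the yz-plane
    frame1 = np.vstack([a, b])
    shift = np.array([displacement / 2.0, 0.0, 0.0])
    frame2 = np.vstack([a + shift, b - shift])
    n = 2 * N_block
    return Trajectory(
        [Frame(frame1, np.arange(n)), Frame(frame2, np.arange(n))], dt=dt
    )


# ---------------------------------------------------------------------------
# Sequence files: one line of H/P characters per sequence
# ---------------------------------------------------------------------------

def write_hp_sequences(seqs: list[HPSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(s.beads + "\n")


def read_hp_sequences(path: str | Path) -> list[HPSequence]:
    with open(path) as fh:
        return [HPSequence(line.strip()) for line in fh if line.strip()]
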