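"""Residue-domain detection and scale-free size statistics.

A residue domain is a transient cluster of residues that are mutually
interconnected by contacts: two residues are in contact when any atom pair
between them lies closer than 0.35 nm, contacts between sequence neighbours
(|i - j| <= 1) being excluded.  Domains are the connected components of the
2-core of the per-frame contact graph (every member keeps at least two
within-domain contacts), and only components of size >= 5 are retained.

Pooled over frames, the domain sizes s of a fluctuating disordered chain
follow a power law P(s) ~ s^(-tau) cut off by the chain length N; writing
P(s, N) ~ s^(-tau) G(s/N) lets distributions from different N collapse onto
the single scaling function G.  Domain compactness is summarised by the
fractal dimension d_f from Rg ~ s^(1/d_f).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import zeta

from .io import Frame, radius_of_gyration, residue_centers

__all__ = [
    "ContactGraph",
    "DomainDecomposition",
    "SizeDistribution",
    "ScalingCollapse",
    "InvolvementProfile",
    "FractalFit",
    "contact_graph",
    "k_core",
    "decompose_domains",
    "size_distribution",
    "size_distribution_from_sizes",
    "power_law_mle",
    "scaling_collapse",
    "fractal_dimension",
    "involvement_profile",
    "domain_prone_region",
]

DEFAULT_CUTOFF_NM = 0.35
DEFAULT_MIN_SIZE = 5


@dataclass
class ContactGraph:
    """Residue contact graph: nodes 0..N-1, undirected non-neighbour edges."""

    n_residues: int
    edges: set  # of tuple (i, j), i < j

    def __post_init__(self) -> None:
        self.edges = {tuple(sorted(e)) for e in self.edges}
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError("edge endpoint out of range")

    @property
    def nodes(self) -> set:
        """Nodes incident to at least one edge."""
        return {v for e in self.edges for v in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_residues))
        g.add_edges_from(self.edges)
        return g


@dataclass
class DomainDecomposition:
    """Residue domains of one frame, sorted by decreasing size."""

    frame_index: int
    domains: list  # of frozenset of residue indices
    n_residues: int

    def __post_init__(self) -> None:
        self.domains = sorted(
            (frozenset(d) for d in self.domains),
            key=lambda d: (-len(d), min(d)),
        )
        seen: set = set()
        for d in self.domains:
            if seen & d:
                raise ValueError("domains must be pairwise disjoint")
            seen |= d

    @property
    def sizes(self) -> list[int]:
        return [len(d) for d in self.domains]

    @property
    def dominant_domains(self) -> list:
        """All domains tied for the largest size (empty list if no domains)."""
        if not self.domains:
            return []
        smax = len(self.domains[0])
        return [d for d in self.domains if len(d) == smax]


@dataclass
class SizeDistribution:
    """Pooled domain-size statistics for one system of N residues."""

    sizes: np.ndarray            # unique observed sizes, increasing
    counts: np.ndarray           # occurrences per size
    N: int
    tau_hat: float | None = None
    fit_range: tuple | None = None
    fit_refused: str | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_domains(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot else self.counts


@dataclass
class ScalingCollapse:
    """Rescaled curves (s/N, P(s, N) s^tau) and their mutual spread."""

    tau: float
    curves: list            # of (x, y) arrays per input distribution
    grid: np.ndarray        # common s/N grid used for scoring
    collapse_score: float   # mean squared log10-difference across curves


@dataclass
class InvolvementProfile:
    """Per-residue fraction of frames spent in the dominant domain."""

    involvement: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.involvement = np.asarray(self.involvement, dtype=float)
        if np.any((self.involvement < 0) | (self.involvement > 1)):
            raise ValueError("involvement values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.involvement)


@dataclass
class FractalFit:
    """Fit of log Rg vs log s: d_f = 1/slope."""

    d_f: float | None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n_domains: int = 0
    refused: str | None = None


# ---------------------------------------------------------------------------

def contact_graph(frame: Frame, cutoff: float = DEFAULT_CUTOFF_NM,
                  exclude_neighbors: int = 1) -> ContactGraph:
    """All-atom residue contact graph.

    Edge (i, j) iff |i - j| > exclude_neighbors and the minimum atom-pair
    distance is strictly below ``cutoff`` (nm).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(frame.coordinates)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    edges: set = set()
    if len(pairs):
        d = np.linalg.norm(
            frame.coordinates[pairs[:, 0]] - frame.coordinates[pairs[:, 1]], axis=1
        )
        pairs = pairs[d < cutoff]  # enforce strict inequality
        ri = frame.residue_indices[pairs[:, 0]]
        rj = frame.residue_indices[pairs[:, 1]]
        keep = np.abs(ri - rj) > exclude_neighbors
        lo = np.minimum(ri[keep], rj[keep])
        hi = np.maximum(ri[keep], rj[keep])
        edges = set(zip(lo.tolist(), hi.tolist()))
    return ContactGraph(n_residues=frame.residue_count, edges=edges)


def k_core(graph: ContactGraph, k: int = 2) -> ContactGraph:
    """Maximal subgraph in which every node keeps degree >= k.

    Equivalent to recursively peeling nodes of degree < k; the result does not
    depend on the removal order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    core = nx.k_core(graph.to_networkx(), k=k)
    return ContactGraph(
        n_residues=graph.n_residues,
        edges={tuple(sorted(e)) for e in core.edges()},
    )


def decompose_domains(frame: Frame, cutoff: float = DEFAULT_CUTOFF_NM,
                      min_size: int = DEFAULT_MIN_SIZE,
                      exclude_neighbors: int = 1,
                      frame_index: int = 0) -> DomainDecomposition:
    """Connected components of the contact graph's 2-core, size >= min_size."""
    core = k_core(contact_graph(frame, cutoff, exclude_neighbors), k=2)
    g = nx.Graph()
    g.add_edges_from(core.edges)
    domains = [
        frozenset(comp) for comp in nx.connected_components(g)
        if len(comp) >= min_size
    ]
    return DomainDecomposition(
        frame_index=frame_index, domains=domains, n_residues=frame.residue_count
    )


def size_distribution(decomps: list[DomainDecomposition], N: int,
                      fit_range: tuple | None = None,
                      bins_per_decade: int = 8,
                      min_domains_for_fit: int = 20) -> SizeDistribution:
    """Pool domain sizes over frames and fit P(s) ~ s^(-tau).

    tau is estimated by least squares on the log-binned size density over
    ``fit_range`` (default [5, 0.3 N], avoiding the finite-size tail).  With
    fewer than ``min_domains_for_fit`` pooled domains, or a degenerate size
    support, the distribution is returned with the fit refused and the reason
    recorded in ``fit_refused``.
    """
    pooled = np.concatenate([np.asarray(d.sizes, dtype=int) for d in decomps]) \
        if decomps else np.array([], dtype=int)
    return size_distribution_from_sizes(pooled, N, fit_range, bins_per_decade,
                                        min_domains_for_fit)


def size_distribution_from_sizes(pooled: np.ndarray, N: int,
                                 fit_range: tuple | None = None,
                                 bins_per_decade: int = 8,
                                 min_domains_for_fit: int = 20
                                 ) -> SizeDistribution:
    """As :func:`size_distribution`, from an already-pooled size sample."""
    pooled = np.asarray(pooled, dtype=int)
    if pooled.size:
        sizes, counts = np.unique(pooled, return_counts=True)
    else:
        sizes, counts = np.array([], dtype=int), np.array([], dtype=float)
    dist = SizeDistribution(sizes=sizes, counts=counts, N=N)

    if fit_range is None:
        fit_range = (DEFAULT_MIN_SIZE, max(DEFAULT_MIN_SIZE + 1, 0.3 * N))
    dist.fit_range = (float(fit_range[0]), float(fit_range[1]))

    if pooled.size < min_domains_for_fit:
        dist.fit_refused = (
            f"only {pooled.size} pooled domains (< {min_domains_for_fit})"
        )
        return dist
    if len(np.unique(pooled)) < 3:
        dist.fit_refused = "degenerate size support (< 3 distinct sizes)"
        return dist

    in_range = pooled[(pooled >= fit_range[0]) & (pooled <= fit_range[1])]
    if in_range.size < min_domains_for_fit:
        dist.fit_refused = "too few domains inside fit_range"
        return dist
    s_rep, pmf = _log_binned_pmf(
        dist.sizes, dist.probabilities, bins_per_decade,
        int(np.ceil(fit_range[0])), int(np.floor(min(fit_range[1],
                                                     in_range.max()))))
    if len(s_rep) < 3:
        dist.fit_refused = "fewer than 3 occupied log bins"
        return dist
    res = stats.linregress(np.log10(s_rep), np.log10(pmf))
    dist.tau_hat = -float(res.slope)
    return dist


def _log_binned_pmf(sizes: np.ndarray, probabilities: np.ndarray,
                    bins_per_decade: int, s_lo: int, s_hi: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Log-binned probability mass function over integer sizes.

    Each bin's ordinate is the average mass per integer size it covers —
    sizes are integers, so dividing by continuous bin width would bias the
    slope at small s where a log bin holds only one or two integers.  The
    abscissa is the geometric mean of the bin's integers.  Returns occupied
    bins only.
    """
    if s_hi < s_lo:
        return np.array([]), np.array([])
    support = np.arange(s_lo, s_hi + 1)
    mass = np.zeros(len(support))
    sel = (sizes >= s_lo) & (sizes <= s_hi)
    mass[np.searchsorted(support, sizes[sel])] = probabilities[sel]
    bin_idx = np.floor(np.log10(support) * bins_per_decade).astype(int)
    bin_idx -= bin_idx.min()
    nb = bin_idx.max() + 1
    n_ints = np.bincount(bin_idx, minlength=nb).astype(float)
    bin_mass = np.bincount(bin_idx, weights=mass, minlength=nb)
    sum_logs = np.bincount(bin_idx, weights=np.log10(support), minlength=nb)
    keep = (n_ints > 0) & (bin_mass > 0)
    s_rep = 10.0 ** (sum_logs[keep] / n_ints[keep])
    pmf = bin_mass[keep] / n_ints[keep]
    return s_rep, pmf


def power_law_mle(sizes: np.ndarray, s_min: int = DEFAULT_MIN_SIZE) -> float:
    """Discrete power-law MLE for tau (Clauset-style), as a cross-check.

    Maximises the discrete power-law likelihood with the Hurwitz zeta
    normaliser over s >= s_min; upper truncation is ignored, so on strongly
    finite-size-cut data this over-estimates tau relative to the log-binned
    least-squares fit.
    """
    s = np.asarray(sizes, dtype=float)
    s = s[s >= s_min]
    if s.size < 10:
        raise ValueError("need at least 10 sizes above s_min")
    sum_log = np.log(s).sum()
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda t: s.size * np.log(zeta(t, s_min)) + t * sum_log,
        bounds=(1.01, 6.0), method="bounded",
    )
    return float(res.x)


def scaling_collapse(dists: list[SizeDistribution], tau: float,
                     n_grid: int = 20,
                     bins_per_decade: int = 8) -> ScalingCollapse:
    """Rescale each distribution to (s/N, P(s) s^tau) and score the collapse.

    Each distribution is first log-binned (the raw per-size mass is far too
    noisy in the finite-size tail) and normalized so its maximum is one: the
    probability normalization constant otherwise carries an N-dependence near
    tau = 1 that offsets the curves vertically even at the true exponent.
    The rescaled curves are then interpolated (log-log, linear) onto a common
    log-spaced grid of s/N values covered by every curve, and the score is
    the mean squared log10-difference of each curve from the across-curve
    mean.  Identical rescaled curves give score 0.
    """
    if len(dists) < 2:
        raise ValueError("scaling_collapse needs at least 2 distributions")
    curves = []
    for d in dists:
        if not len(d.sizes):
            raise ValueError("each distribution must contain observed sizes")
        s_rep, pmf = _log_binned_pmf(
            d.sizes, d.probabilities, bins_per_decade,
            int(d.sizes.min()), int(d.sizes.max()))
        x = s_rep / d.N
        y = (pmf / pmf.max()) * s_rep**tau
        if len(x) < 2:
            raise ValueError("each distribution needs >= 2 occupied bins")
        curves.append((x, y))
    lo = max(c[0][0] for c in curves)
    hi = min(c[0][-1] for c in curves)
    if not lo < hi:
        raise ValueError("distributions share no overlapping s/N range")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    logy = np.array([
        np.interp(np.log10(grid), np.log10(x), np.log10(y))
        for x, y in curves
    ])
    score = float(np.mean((logy - logy.mean(axis=0)) ** 2))
    return ScalingCollapse(tau=tau, curves=curves, grid=grid,
                           collapse_score=score)


def fractal_dimension(decomps: list[DomainDecomposition],
                      frames: list[Frame]) -> FractalFit:
    """d_f from Rg ~ s^(1/d_f) over all retained domains.

    For each domain the radius of gyration of its residue centers is
    computed; log Rg is regressed on log s.  The fit is refused (d_f None,
    reason recorded) with fewer than 10 domains or less than half a decade of
    size span.
    """
    if len(decomps) != len(frames):
        raise ValueError("decomps and frames must match one-to-one")
    s_list, rg_list = [], []
    for dec, frame in zip(decomps, frames):
        if not dec.domains:
            continue
        centers = residue_centers(frame)
        for dom in dec.domains:
            idx = sorted(dom)
            rg = radius_of_gyration(centers[idx])
            if rg > 0:
                s_list.append(len(dom))
                rg_list.append(rg)
    n = len(s_list)
    if n < 10:
        return FractalFit(d_f=None, n_domains=n,
                          refused=f"only {n} domains (< 10)")
    s = np.asarray(s_list, dtype=float)
    if s.max() / s.min() < 10 ** 0.5:
        return FractalFit(d_f=None, n_domains=n,
                          refused="size span below half a decade")
    res = stats.linregress(np.log10(s), np.log10(rg_list))
    return FractalFit(
        d_f=1.0 / float(res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_domains=n,
    )


def involvement_profile(decomps: list[DomainDecomposition]) -> InvolvementProfile:
    """Fraction of frames each residue spends in the dominant (largest) domain.

    Frames without domains count in the denominator; when several domains tie
    for the largest size, membership in any of them counts.
    """
    if not decomps:
        raise ValueError("involvement_profile requires at least one frame")
    n = decomps[0].n_residues
    hits = np.zeros(n)
    for dec in decomps:
        if dec.n_residues != n:
            raise ValueError("all decompositions must share the same N")
        members: set = set()
        for dom in dec.dominant_domains:
            members |= dom
        for i in members:
            hits[i] += 1
    return InvolvementProfile(involvement=hits / len(decomps),
                              n_frames=len(decomps))


def domain_prone_region(profile: InvolvementProfile) -> tuple[int, int]:
    """Contiguous window of length round(N/3) maximising mean involvement.

    Ties break toward the smallest start index.  Returns inclusive
    (start, end) residue indices.
    """
    n = len(profile)
    if n < 6:
        raise ValueError("profile too short (N < 6)")
    w = int(round(n / 3))
    csum = np.concatenate([[0.0], np.cumsum(profile.involvement)])
    window_sums = csum[w:] - csum[:-w]
    # first window within rounding noise of the maximum (ties -> smallest start)
    start = int(np.argmax(window_sums >= window_sums.max() - 1e-9))
    return start, start + w - 1
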