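"""Residue domains: contacts, 2-core, size statistics, involvement.

Brute-force oracles: an O(N^2 * atoms^2) double loop for contacts, an
iterate-to-fixed-point peeler (in randomized orders) for the k-core, and an
exhaustive window scan for the domain-prone region.
"""


import networkx as nx
import numpy as np
import pytest

import idpcrit as ic
from idpcrit.domains import ContactGraph, DomainDecomposition
from idpcrit.io import Frame

from conftest import make_bead_frame, random_rotation


def brute_force_contacts(frame, cutoff, exclude_neighbors=1):
    n = frame.residue_count
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if j - i <= exclude_neighbors:
                continue
            ai = frame.coordinates[frame.residue_indices == i]
            aj = frame.coordinates[frame.residue_indices == j]
            dmin = min(
                np.linalg.norm(a - b) for a in ai for b in aj
            )
            if dmin < cutoff:
                edges.add((i, j))
    return edges


def brute_force_k_core(n, edges, k, order=None):
    """Peel nodes of degree < k one at a time in the given order until fixed."""
    adj = {i: set() for i in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    alive = set(range(n))
    changed = True
    while changed:
        changed = False
        candidates = sorted(alive) if order is None else [
            v for v in order if v in alive
        ]
        for v in candidates:
            if len(adj[v] & alive) < k:
                alive.discard(v)
                changed = True
    return {v for v in alive if len(adj[v] & alive) >= k and adj[v] & alive}


class TestContactGraph:
    def test_beads_on_a_line_no_contacts(self):
        frame = make_bead_frame(np.c_[np.arange(10.0), np.zeros(10), np.zeros(10)])
        g = ic.contact_graph(frame, cutoff=0.35)
        assert g.edges == set()

    def test_neighbor_exclusion(self):
        """Contact below 0.35 nm counts only beyond sequence neighbors."""
        pts = np.array([[0, 0, 0], [0.30, 0, 0], [100, 0, 0]])
        g = ic.contact_graph(make_bead_frame(pts), cutoff=0.35)
        assert g.edges == set()  # residues 0-1 adjacent: excluded
        pts = np.array([[0, 0, 0], [100, 0, 0], [0.30, 0, 0]])
        g = ic.contact_graph(make_bead_frame(pts), cutoff=0.35)
        assert g.edges == {(0, 2)}

    def test_strict_inequality_at_cutoff(self):
        pts = np.array([[0, 0, 0], [50, 0, 0], [0.35, 0, 0]])
        g = ic.contact_graph(make_bead_frame(pts), cutoff=0.35)
        assert g.edges == set()

    def test_matches_brute_force_multiatom(self, rng):
        """20 residues x 3 atoms vs O(N^2 atoms^2) double loop."""
        n_res, n_atoms = 20, 3
        coords = rng.uniform(0, 2.0, size=(n_res * n_atoms, 3))
        frame = Frame(coords, np.repeat(np.arange(n_res), n_atoms))
        for cutoff in (0.3, 0.5, 0.8):
            assert ic.contact_graph(frame, cutoff).edges == \
                brute_force_contacts(frame, cutoff)

    def test_cutoff_monotonicity(self, rng):
        frame = make_bead_frame(rng.uniform(0, 2.0, size=(25, 3)))
        prev = set()
        for cutoff in (0.2, 0.4, 0.6, 0.9):
            edges = ic.contact_graph(frame, cutoff).edges
            assert prev <= edges
            prev = edges


class TestKCore:
    def test_triangle_is_fixed_point(self):
        g = ContactGraph(5, {(0, 2), (2, 4), (0, 4)})
        core = ic.k_core(g, 2)
        assert core.edges == g.edges

    def test_path_peels_to_nothing(self):
        g = ContactGraph(8, {(0, 2), (2, 4), (4, 6)})
        assert ic.k_core(g, 2).edges == set()

    def test_random_graphs_match_peeling_oracle(self, rng):
        """200 Erdos-Renyi graphs vs fixed-point peeling, randomized orders."""
        for trial in range(200):
            n = int(rng.integers(5, 26))
            p = rng.choice([0.1, 0.2, 0.3])
            g_nx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            edges = {tuple(sorted(e)) for e in g_nx.edges()}
            core = ic.k_core(ContactGraph(n, edges), 2)
            order = list(rng.permutation(n))
            oracle_nodes = brute_force_k_core(n, edges, 2, order)
            assert core.nodes == oracle_nodes

    def test_removal_order_independence(self, rng):
        n = 20
        g_nx = nx.gnp_random_graph(n, 0.25, seed=42)
        edges = {tuple(sorted(e)) for e in g_nx.edges()}
        results = {
            frozenset(brute_force_k_core(n, edges, 2, list(rng.permutation(n))))
            for _ in range(20)
        }
        assert len(results) == 1
        assert ic.k_core(ContactGraph(n, edges), 2).nodes == set(next(iter(results)))

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            ic.k_core(ContactGraph(3, set()), 0)


class TestDecomposeDomains:
    def test_planted_clusters_recovered(self):
        spec = ic.PlantedConformerSpec(
            N=30, cluster_assignments=[set(range(2, 10)), set(range(15, 23))]
        )
        frame = ic.planted_domain_frame(spec, seed=1)
        dec = ic.decompose_domains(frame)
        assert sorted(dec.sizes) == [8, 8]
        assert set(dec.domains) == set(spec.cluster_assignments)

    def test_extended_chain_no_domains(self):
        frame = make_bead_frame(np.c_[np.arange(40) * 0.5,
                                      np.zeros(40), np.zeros(40)])
        assert ic.decompose_domains(frame).domains == []

    def test_size_four_plant_below_threshold(self):
        """Domains must exceed size 4; a 4-residue clique yields nothing."""
        spec = ic.PlantedConformerSpec(
            N=20, cluster_assignments=[{3, 7, 11, 15}]
        )
        frame = ic.planted_domain_frame(spec, seed=2)
        assert ic.decompose_domains(frame, min_size=5).domains == []
        assert len(ic.decompose_domains(frame, min_size=4).domains) == 1

    def test_rigid_transform_invariance(self, rng):
        spec = ic.PlantedConformerSpec(
            N=25, cluster_assignments=[set(range(5, 12))]
        )
        frame = ic.planted_domain_frame(spec, seed=3)
        moved = frame.transformed(random_rotation(rng), rng.normal(size=3))
        assert ic.decompose_domains(frame).domains == \
            ic.decompose_domains(moved).domains

    def test_members_have_internal_degree_two(self, rng):
        """Every domain member keeps >= 2 within-domain contacts."""
        frame = make_bead_frame(rng.uniform(0, 1.2, size=(40, 3)))
        dec = ic.decompose_domains(frame, cutoff=0.5)
        g = ic.contact_graph(frame, cutoff=0.5)
        for dom in dec.domains:
            for v in dom:
                deg = sum(
                    1 for (a, b) in g.edges
                    if (a == v and b in dom) or (b == v and a in dom)
                )
                assert deg >= 2


class TestSizeDistribution:
    def test_degenerate_distribution_fit_refused(self):
        decs = [
            DomainDecomposition(k, [frozenset(range(10))], 64)
            for k in range(30)
        ]
        dist = ic.size_distribution(decs, N=64)
        assert dist.tau_hat is None
        assert "degenerate" in dist.fit_refused

    def test_too_few_domains_fit_refused(self):
        decs = [DomainDecomposition(0, [frozenset(range(7))], 64)]
        dist = ic.size_distribution(decs, N=64)
        assert dist.tau_hat is None
        assert dist.n_domains == 1

    def test_merging_adds_counts(self):
        a = [DomainDecomposition(0, [frozenset(range(6))], 64)]
        b = [DomainDecomposition(1, [frozenset(range(6)),
                                     frozenset(range(10, 17))], 64)]
        merged = ic.size_distribution(a + b, N=64)
        sep_a = ic.size_distribution(a, N=64)
        sep_b = ic.size_distribution(b, N=64)
        for s, c in zip(merged.sizes, merged.counts):
            ca = dict(zip(sep_a.sizes, sep_a.counts)).get(s, 0)
            cb = dict(zip(sep_b.sizes, sep_b.counts)).get(s, 0)
            assert c == ca + cb

    def test_tau_recovery(self):
        sizes = ic.power_law_sizes(1.15, 5, 200, 10_000, seed=3)
        dist = ic.size_distribution_from_sizes(sizes, N=200)
        assert 1.00 <= dist.tau_hat <= 1.30


def sample_cutoff_power_law(tau, N, n, rng, g_scale=0.3, family="exp"):
    """Draws from P(s) ~ s^-tau G(s/N) with G exponential or sharp."""
    s = np.arange(5, N + 1)
    if family == "exp":
        w = s.astype(float) ** -tau * np.exp(-s / (g_scale * N))
    else:  # sharp cutoff family
        w = s.astype(float) ** -tau * (s <= g_scale * N)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return s[np.searchsorted(cdf, rng.random(n))]


class TestScalingCollapse:
    def test_identical_distributions_score_zero(self):
        sizes = ic.power_law_sizes(1.15, 5, 100, 2000, seed=0)
        d = ic.size_distribution_from_sizes(sizes, N=100)
        res = ic.scaling_collapse([d, d], tau=1.15)
        assert res.collapse_score == pytest.approx(0.0, abs=1e-15)

    def test_true_tau_beats_offsets_majority(self):
        """Score at generator tau beats tau +/- 0.5 in >= 16/20 replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dists = [
                ic.size_distribution_from_sizes(
                    sample_cutoff_power_law(1.15, N, 3000, rng), N=N
                )
                for N in (64, 128, 256)
            ]
            scores = {
                tau: ic.scaling_collapse(dists, tau).collapse_score
                for tau in (0.65, 1.15, 1.65)
            }
            if scores[1.15] < scores[0.65] and scores[1.15] < scores[1.65]:
                wins += 1
        assert wins >= 16

    def test_mismatched_g_families_score_higher(self):
        """Swapping one curve's cutoff family G degrades the collapse."""
        rng = np.random.default_rng(11)
        matched = [
            ic.size_distribution_from_sizes(
                sample_cutoff_power_law(1.15, N, 4000, rng, family="exp"), N=N
            )
            for N in (64, 128, 256)
        ]
        rng2 = np.random.default_rng(11)
        mixed = [matched[0], matched[1],
                 ic.size_distribution_from_sizes(
                     sample_cutoff_power_law(1.15, 256, 4000, rng2,
                                             g_scale=0.3, family="sharp"),
                     N=256)]
        s_match = ic.scaling_collapse(matched, 1.15).collapse_score
        s_mixed = ic.scaling_collapse(mixed, 1.15).collapse_score
        assert s_mixed > s_match

    def test_fewer_than_two_rejected(self):
        sizes = ic.power_law_sizes(1.15, 5, 100, 500, seed=0)
        d = ic.size_distribution_from_sizes(sizes, N=100)
        with pytest.raises(ValueError):
            ic.scaling_collapse([d], 1.15)


def _single_domain_case(points_list):
    """Build (decomps, frames) where each frame is one whole-chain domain."""
    decomps, frames = [], []
    for k, pts in enumerate(points_list):
        frames.append(make_bead_frame(pts))
        decomps.append(
            DomainDecomposition(k, [frozenset(range(len(pts)))], len(pts))
        )
    return decomps, frames


class TestFractalDimension:
    def test_rod_limit(self):
        sizes = np.unique(np.logspace(np.log10(8), np.log10(64), 12).astype(int))
        pts = [np.c_[np.arange(s) * 0.3, np.zeros(s), np.zeros(s)]
               for s in sizes]
        fit = ic.fractal_dimension(*_single_domain_case(pts))
        assert fit.d_f == pytest.approx(1.0, abs=0.02)

    def test_gaussian_chain_domains(self):
        sizes = np.unique(
            np.logspace(np.log10(8), np.log10(128), 15).astype(int))
        pts = []
        for rep in range(20):
            for s in sizes:
                pts.append(ic.gaussian_chain(int(s), 0.38,
                                             seed=1000 * rep + s).coordinates)
        fit = ic.fractal_dimension(*_single_domain_case(pts))
        assert 1.8 <= fit.d_f <= 2.2

    def test_uniform_ball_limit(self, rng):
        pts = []
        for s in np.unique(np.logspace(np.log10(20), np.log10(200), 12).astype(int)):
            u = rng.normal(size=(s, 3))
            u /= np.linalg.norm(u, axis=1)[:, None]
            R = s ** (1 / 3)
            pts.append(u * R * rng.random(s)[:, None] ** (1 / 3))
        fit = ic.fractal_dimension(*_single_domain_case(pts))
        assert fit.d_f == pytest.approx(3.0, abs=0.3)

    def test_refusal_on_narrow_span(self):
        pts = [np.random.default_rng(k).normal(size=(10, 3)) for k in range(12)]
        fit = ic.fractal_dimension(*_single_domain_case(pts))
        assert fit.d_f is None
        assert "span" in fit.refused


class TestInvolvement:
    def test_planted_sixty_of_hundred(self):
        dom = frozenset(range(5, 15))
        decs = []
        for k in range(100):
            domains = [dom] if k < 60 else []
            decs.append(DomainDecomposition(k, domains, 30))
        prof = ic.involvement_profile(decs)
        assert np.allclose(prof.involvement[5:15], 0.6)
        assert np.allclose(prof.involvement[:5], 0.0)
        assert np.allclose(prof.involvement[15:], 0.0)

    def test_always_and_never(self):
        decs = [
            DomainDecomposition(k, [frozenset(range(0, 6))], 12)
            for k in range(10)
        ]
        prof = ic.involvement_profile(decs)
        assert prof.involvement[0] == 1.0
        assert prof.involvement[11] == 0.0

    def test_tied_dominant_domains_both_count(self):
        decs = [DomainDecomposition(
            0, [frozenset(range(0, 6)), frozenset(range(6, 12))], 12)]
        prof = ic.involvement_profile(decs)
        assert np.allclose(prof.involvement, 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ic.involvement_profile([])


class TestDomainProneRegion:
    def test_unique_peak(self):
        inv = np.zeros(30)
        inv[10:20] = 1.0
        prof = ic.InvolvementProfile(inv, 100)
        assert ic.domain_prone_region(prof) == (10, 19)

    def test_uniform_ties_to_start(self):
        prof = ic.InvolvementProfile(np.full(30, 0.4), 100)
        assert ic.domain_prone_region(prof) == (0, 9)

    def test_against_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(9, 120))
            inv = rng.random(n)
            prof = ic.InvolvementProfile(inv, 10)
            w = int(round(n / 3))
            means = [inv[s:s + w].mean() for s in range(n - w + 1)]
            best = int(np.argmax(means))
            assert ic.domain_prone_region(prof) == (best, best + w - 1)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            ic.domain_prone_region(ic.InvolvementProfile(np.zeros(5), 1))
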