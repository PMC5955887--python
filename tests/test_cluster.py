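"""PCCA+ metastability analysis, components, coarse-graining and TPT."""

import numpy as np
import pytest

import dimerkin as dk
from dimerkin.cluster import (
    _angular_flatness,
    assemble_macrostates,
    coarse_grain,
    coarse_grain_projection,
    committor,
    disconnected_components,
    flux_partition,
    pcca_plus,
    select_umbrella_centers,
    select_unbound,
    swap_permutation,
)
from dimerkin.msm import stationary_distribution


def _block_T(sizes, coupling, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    W = np.full((n, n), coupling)
    i0 = 0
    for s in sizes:
        W[i0 : i0 + s, i0 : i0 + s] = rng.uniform(0.5, 1.0, (s, s))
        i0 += s
    W = 0.5 * (W + W.T)
    T = W / W.sum(axis=1, keepdims=True)
    return T, stationary_distribution(T)


class TestPCCA:
    def test_block_diagonal_recovery(self):
        T, pi = _block_T([4, 3, 5], 1e-4)
        labels = pcca_plus(T, 3, pi=pi).labels
        blocks = np.repeat([0, 1, 2], [4, 3, 5])
        for b in range(3):
            assert len(set(labels[blocks == b])) == 1

    def test_memberships_are_probabilities(self):
        T, pi = _block_T([4, 4], 1e-3)
        chi = pcca_plus(T, 2, pi=pi).memberships
        assert np.all(chi >= 0)
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-12)

    def test_single_cluster(self):
        T, pi = _block_T([5], 1e-3)
        cl = pcca_plus(T, 1, pi=pi)
        assert set(cl.labels.tolist()) == {0}

    def test_too_many_clusters_rejected(self):
        T, pi = _block_T([3], 1e-3)
        with pytest.raises(ValueError):
            pcca_plus(T, 7, pi=pi)


def _labelled_model(seed=0):
    """Hand-built microstate model: two bound basins plus a diffuse unbound set.

    States 0-3: basin at (α1, α2) ≈ (0.3, 2.8) (asymmetric, C0pi);
    states 4-7: mirror basin (2.8, 0.3); states 8-19: unbound, d > 4.5 with
    angles spread over all quadrants.
    """
    rng = np.random.default_rng(seed)
    n = 20
    W = np.full((n, n), 1e-12)
    W[0:4, 0:4] = rng.uniform(0.5, 1, (4, 4))
    W[4:8, 4:8] = rng.uniform(0.5, 1, (4, 4))
    W[8:, 8:] = rng.uniform(0.5, 1, (12, 12))
    W[0:4, 8:] = rng.uniform(0.005, 0.01, (4, 12))
    W[4:8, 8:] = rng.uniform(0.005, 0.01, (4, 12))
    W = 0.5 * (W + W.T)
    T = W / W.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    # basin B and the unbound states are exact swap mirrors of their partners
    a1_A = 0.3 + rng.normal(0, 0.05, 4)
    a2_A = 2.8 + rng.normal(0, 0.05, 4)
    d_unb = np.repeat(rng.uniform(4.6, 7.4, 6), 2)
    a1_unb = np.empty(12)
    a2_unb = np.empty(12)
    a1_unb[0::2] = [0.4, 1.2, 1.9, 2.7, 0.8, 2.2]
    a2_unb[0::2] = [0.5, 1.8, 1.1, 2.6, 2.3, 0.7]
    a1_unb[1::2] = a2_unb[0::2]
    a2_unb[1::2] = a1_unb[0::2]
    d = np.concatenate([np.full(8, 3.0), d_unb])
    a1 = np.concatenate([a1_A, a2_A, a1_unb])
    a2 = np.concatenate([a2_A, a1_A, a2_unb])
    cvs = np.column_stack([d, a1, a2])
    counts = np.rint(W * 1e6).astype(int)
    return T, pi, cvs, counts


class TestUnboundSelection:
    def test_unbound_cluster_found(self):
        T, pi, cvs, counts = _labelled_model()
        n, c, cl = select_unbound(T, pi, cvs)
        members = cl.cluster_members(c)
        assert set(members.tolist()) == set(range(8, 20))

    def test_all_bound_system_errors(self):
        T, pi = _block_T([4, 4], 1e-3)
        cvs = np.column_stack([np.full(8, 3.0), np.full(8, 0.3), np.full(8, 0.4)])
        with pytest.raises(ValueError, match="no unbound cluster"):
            select_unbound(T, pi, cvs, n_max=6)

    def test_flatness_criterion(self):
        vals = np.array([0.4, 1.2, 1.9, 2.7])
        a1, a2 = np.meshgrid(vals, vals)
        w = np.full(16, 1 / 16)
        assert _angular_flatness(a1.ravel(), a2.ravel(), w)
        a_peaked = np.full(16, 0.3)
        assert not _angular_flatness(a_peaked, a_peaked, w)


class TestComponents:
    def test_two_planted_components(self):
        T, pi, cvs, counts = _labelled_model()
        n, c, cl = select_unbound(T, pi, cvs)
        dec = disconnected_components(counts, cl, c, pi, cvs)
        main = [l for l in dec.labels if l != "other"]
        assert sorted(main) == ["C0pi", "Cpi0"]

    def test_fully_connected_bound_single_component(self):
        rng = np.random.default_rng(1)
        n = 8
        W = rng.uniform(0.5, 1, (n, n))
        W = 0.5 * (W + W.T)
        T = W / W.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
        cvs = np.column_stack([np.full(n, 3.0), np.full(n, 0.3), np.full(n, 0.3)])
        counts = np.rint(W * 1e4).astype(int)
        cl = pcca_plus(T, 3, pi=pi)
        dec = disconnected_components(counts, cl, cl.labels[-1], pi, cvs)
        assert len(dec.components) <= 2  # everything except the excluded cluster

    def test_labels_follow_circular_means(self):
        T, pi, cvs, counts = _labelled_model()
        n, c, cl = select_unbound(T, pi, cvs)
        dec = disconnected_components(counts, cl, c, pi, cvs)
        for comp, lbl in zip(dec.components, dec.labels):
            if lbl == "other":
                continue
            members = np.flatnonzero(np.isin(cl.labels, list(comp)))
            m1 = np.average(cvs[members, 1], weights=pi[members])
            expect = "C" + ("0" if m1 < np.pi / 2 else "pi")
            assert lbl.startswith(expect)


class TestMacrostates:
    def test_asymmetric_pairing(self):
        T, pi, cvs, counts = _labelled_model()
        n, c, cl = select_unbound(T, pi, cvs)
        dec = disconnected_components(counts, cl, c, pi, cvs)
        macs = assemble_macrostates(dec, cvs, pi)
        # the two mirror basins merge into one macrostate spanning two clusters
        paired = [m for m in macs if len(m.clusters) == 2]
        assert len(paired) == 1
        assert set(paired[0].microstates.tolist()) == set(range(8))

    def test_swap_permutation_involution(self):
        T, pi, cvs, counts = _labelled_model()
        perm = swap_permutation(cvs)
        assert np.array_equal(perm[perm], np.arange(len(cvs)))


class TestCoarseGrain:
    def test_identity_partition_returns_T(self):
        T, pi = _block_T([3, 3], 0.05, seed=2)
        cg = coarse_grain(T, pi, [[i] for i in range(6)])
        assert np.abs(cg.T_cg - T).max() < 1e-10

    def test_block_uncoupled_gives_identity(self):
        rng = np.random.default_rng(3)
        W = np.zeros((6, 6))
        W[:3, :3] = rng.uniform(0.5, 1, (3, 3))
        W[3:, 3:] = rng.uniform(0.5, 1, (3, 3))
        W = 0.5 * (W + W.T)
        T = W / W.sum(axis=1, keepdims=True)
        # any mixture of the per-block stationary laws is stationary
        pi = np.concatenate([
            0.4 * W[:3, :3].sum(1) / W[:3, :3].sum(),
            0.6 * W[3:, 3:].sum(1) / W[3:, 3:].sum(),
        ])
        cg = coarse_grain(T, pi, [[0, 1, 2], [3, 4, 5]])
        assert np.abs(cg.T_cg - np.eye(2)).max() < 1e-10

    def test_exact_stationarity_and_rows(self):
        rng = np.random.default_rng(4)
        for n, k in [(6, 2), (9, 3), (12, 4)]:
            W = rng.uniform(0.1, 1, (n, n))
            W = 0.5 * (W + W.T)
            T = W / W.sum(axis=1, keepdims=True)
            pi = stationary_distribution(T)
            cg = coarse_grain(T, pi, np.array_split(np.arange(n), k))
            assert np.abs(cg.T_cg.sum(axis=1) - 1).max() < 1e-10
            agg = np.array([pi[p].sum() for p in np.array_split(np.arange(n), k)])
            assert np.abs(cg.pi_cg - agg).max() < 1e-14
            assert np.abs(stationary_distribution(cg.T_cg) - agg).max() < 1e-8

    def test_cross_relaxation_preserved(self):
        """The coarse matrix reproduces the slowest cross-group relaxation of
        the full model (spectral oracle)."""
        T, pi = _block_T([3, 3], 1e-3, seed=5)
        cg = coarse_grain(T, pi, [[0, 1, 2], [3, 4, 5]])
        ev_full = np.sort(np.linalg.eigvals(T).real)[::-1]
        ev_cg = np.sort(np.linalg.eigvals(cg.T_cg).real)[::-1]
        assert ev_cg[1] == pytest.approx(ev_full[1], rel=1e-6)

    def test_partition_must_cover(self):
        T, pi = _block_T([3, 3], 0.05)
        with pytest.raises(ValueError, match="cover"):
            coarse_grain(T, pi, [[0, 1], [3, 4, 5]])


class TestCommittor:
    def test_birth_death_closed_form(self):
        n, p, q = 10, 0.4, 0.6
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = q
            if i < n - 1:
                T[i, i + 1] = p
            T[i, i] = 1 - T[i].sum()
        qc = committor(T, [0], [n - 1])
        r = q / p
        expect = (1 - r ** np.arange(n)) / (1 - r ** (n - 1))
        assert np.abs(qc - expect).max() < 1e-12
        assert np.all(np.diff(qc) >= 0)  # monotone along the chain

    def test_boundary_values(self):
        T, pi = _block_T([6], 0.05)
        q = committor(T, [0], [5])
        assert q[0] == 0.0 and q[5] == 1.0
        assert np.all((q >= 0) & (q <= 1))

    def test_symmetric_chain_midpoint(self):
        n = 5
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = 0.5
            if i < n - 1:
                T[i, i + 1] = 0.5
            T[i, i] = 1 - T[i].sum()
        q = committor(T, [0], [n - 1])
        assert q[n // 2] == pytest.approx(0.5)

    def test_invalid_sets(self):
        T, pi = _block_T([4], 0.05)
        with pytest.raises(ValueError):
            committor(T, [0], [0])


class TestUmbrellaCenters:
    def test_threshold_extremes(self):
        T, pi, cvs, counts = _labelled_model()
        comps = [list(range(0, 4)), list(range(4, 8))]
        full = select_umbrella_centers(T, pi, comps, unbound_state=19, threshold=0.0)
        none = select_umbrella_centers(T, pi, comps, unbound_state=19, threshold=1.0)
        assert none["selected"] == []
        q = full["per_component"][0]["committor"]
        expect = set(np.flatnonzero(q > 0).tolist()) - {full["per_component"][0]["sink"]}
        assert expect <= set(full["selected"])

    def test_toy_chain_hand_enumeration(self):
        n = 6
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = 0.3
            if i < n - 1:
                T[i, i + 1] = 0.3
            T[i, i] = 1 - T[i].sum()
        pi = stationary_distribution(T)
        out = select_umbrella_centers(T, pi, [list(range(1, n))], unbound_state=0,
                                      threshold=0.5)
        q = out["per_component"][0]["committor"]
        expect = sorted(set(np.flatnonzero(q > 0.5).tolist()) - {n - 1})
        assert out["selected"] == expect


class TestFluxPartition:
    def test_linear_chain_single_pathway(self):
        n = 3
        T = np.array([[0.8, 0.2, 0.0], [0.1, 0.8, 0.1], [0.0, 0.2, 0.8]])
        pi = stationary_distribution(T)
        out = flux_partition(T, pi, [0], [2])
        assert len(out["pathways"]) == 1
        assert out["pathways"][0]["fraction"] == pytest.approx(1.0)
        assert out["pathways"][0]["path"] == [0, 1, 2]

    def test_parallel_channels_split(self):
        for w1, w2, frac in [(0.5, 0.5, 0.5), (0.9, 0.1, 0.9)]:
            W = np.zeros((4, 4))
            W[0, 1] = W[1, 3] = w1
            W[0, 2] = W[2, 3] = w2
            W = W + W.T + np.eye(4) * 1e-9
            T = W / W.sum(axis=1, keepdims=True)
            pi = stationary_distribution(T)
            out = flux_partition(T, pi, [0], [3])
            fr = sorted(p["fraction"] for p in out["pathways"])[-1]
            assert fr == pytest.approx(frac, abs=1e-10)

    def test_zero_flux_errors(self):
        T = np.eye(3)
        with pytest.raises(ValueError):
            flux_partition(T, np.full(3, 1 / 3), [0], [2])


class TestCoarseVsProjectionCK:
    def test_cross_relaxation_cg_tracks_micro_occupation(self):
        """CG occupation-probability curves track the aggregated microscopic
        curves at least as well as naive projection coarse-graining."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            T, pi = _block_T([4, 4, 4], 10 ** rng.uniform(-4, -2), seed=trial)
            parts = [[0, 1, 2, 3], [4, 5, 6, 7], [8, 9, 10, 11]]
            hs = coarse_grain(T, pi, parts)
            proj = coarse_grain_projection(T, pi, parts)
            dev_hs, dev_pr = occupation_deviation(T, pi, parts, hs.T_cg, proj.T_cg)
            assert dev_hs <= dev_pr + 1e-12


def occupation_deviation(T, pi, parts, T_hs, T_pr, k_max=50):
    """Max deviation of CG set-occupation curves from the aggregated micro curves."""
    m = len(parts)
    A = np.zeros((len(pi), m))
    for a, p in enumerate(parts):
        A[p, a] = 1.0
    # start within each group, distributed by pi
    P0 = []
    for p in parts:
        v = np.zeros(len(pi))
        v[p] = pi[p] / pi[p].sum()
        P0.append(v)
    P0 = np.array(P0)
    dev_hs = dev_pr = 0.0
    cur = P0.copy()
    cg_hs = np.eye(m)
    cg_pr = np.eye(m)
    for k in range(1, k_max + 1):
        cur = cur @ T
        occ_micro = cur @ A
        cg_hs = cg_hs @ T_hs
        cg_pr = cg_pr @ T_pr
        dev_hs = max(dev_hs, np.abs(cg_hs - occ_micro).max())
        dev_pr = max(dev_pr, np.abs(cg_pr - occ_micro).max())
    return dev_hs, dev_pr
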