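"""Multi-ensemble (TRAM) estimation against planted discrete truths."""

import numpy as np
import pytest

import dimerkin as dk
from dimerkin.msm import count_transitions, mle_reversible
from dimerkin.tram import (
    EnsembleData,
    evaluate_bias_energies,
    kT_kJ_per_mol,
    resample_unbound,
    tram_bootstrap,
    tram_estimate,
)


def _truth_data(truth, n_steps, seed0=100, split=1):
    """EnsembleData per ensemble of a DiscreteTruth (bias constant per state)."""
    data = []
    for k in range(truth.n_ensembles):
        traj = dk.sample_chain(truth, k, n_steps, seed=seed0 + k)
        pieces = np.array_split(traj, split)
        data.append(
            EnsembleData(
                bias=None if k == 0 else dk.BiasSpec(center=(3, 0, 0), k_d=1, k_alpha=1),
                dtrajs=list(pieces),
                bias_matrices=[truth.bias_energies[:, p].T for p in pieces],
            )
        )
    return data


class TestBiasEnergies:
    def test_frame_at_center_zero(self):
        tr = dk.CVTrajectory(t=[0.0], d=[3.0], alpha1=[0.5], alpha2=[0.7], dt=1.0)
        spec = dk.BiasSpec(center=(3.0, 0.5, 0.7), k_d=250.0, k_alpha=100.0)
        b = evaluate_bias_energies(tr, [None, spec], kT=1.0)
        assert b[0, 0] == 0.0
        assert b[0, 1] == 0.0

    def test_physical_units_at_310K(self):
        """1 nm from the center along d with k_d = 250 kJ/mol/nm² at 310 K."""
        tr = dk.CVTrajectory(t=[0.0], d=[4.0], alpha1=[0.5], alpha2=[0.7], dt=1.0)
        spec = dk.BiasSpec(center=(3.0, 0.5, 0.7), k_d=250.0, k_alpha=100.0)
        b = evaluate_bias_energies(tr, [spec], kT=kT_kJ_per_mol(310.0))
        assert b[0, 0] == pytest.approx(0.5 * 250.0 / (0.0083145 * 310.0), rel=1e-12)

    def test_doubling_k_doubles_energy(self):
        tr = dk.CVTrajectory(t=[0.0], d=[4.0], alpha1=[1.0], alpha2=[0.2], dt=1.0)
        s1 = dk.BiasSpec(center=(3.0, 0.5, 0.7), k_d=50.0, k_alpha=20.0)
        s2 = dk.BiasSpec(center=(3.0, 0.5, 0.7), k_d=100.0, k_alpha=40.0)
        b = evaluate_bias_energies(tr, [s1, s2])
        assert b[0, 1] == pytest.approx(2 * b[0, 0], rel=1e-12)

    def test_nonfinite_cvs_rejected(self):
        tr = dk.CVTrajectory(t=[0.0], d=[np.nan], alpha1=[0.5], alpha2=[0.7], dt=1.0)
        with pytest.raises(ValueError, match="non-finite"):
            evaluate_bias_energies(tr, [None])


class TestResampleUnbound:
    def test_no_qualifying_identity(self):
        C = np.ones((4, 4), int)
        mapping, dtrajs = resample_unbound([np.array([0, 1, 2, 3])], [2, 3], C)
        assert mapping.tolist() == [0, 1, 2, 3]

    def test_toy_merge_five_of_eight(self):
        """8 unbound states, 5 never exchange with the outside: those merge."""
        n = 11  # 3 bound (0-2) + 8 unbound (3-10)
        C = np.zeros((n, n), int)
        for i in range(3, 11):
            C[i, i] = 10
        for i in range(3, 10):
            C[i, i + 1] = C[i + 1, i] = 5  # chain inside the unbound block
        # states 3, 4, 5 exchange with the bound side; 6..10 never do
        for i in (3, 4, 5):
            C[i, 0] = C[0, i] = 2
        C[0, 1] = C[1, 2] = C[2, 0] = 3
        mapping, dtrajs = resample_unbound(
            [np.arange(n)], unbound_states=range(3, 11), counts=C
        )
        merged_label = mapping[6]
        assert all(mapping[i] == merged_label for i in range(6, 11))
        kept = [mapping[i] for i in (0, 1, 2, 3, 4, 5)]
        assert len(set(kept)) == 6 and merged_label not in kept

    def test_frame_count_conserved(self):
        C = np.zeros((6, 6), int)
        C[:3, :3] = 2
        for i in range(3, 6):
            C[i, i] = 4
        rng = np.random.default_rng(0)
        dtrajs = [rng.integers(0, 6, 50) for _ in range(3)]
        mapping, new = resample_unbound(dtrajs, [3, 4, 5], C)
        assert sum(len(t) for t in new) == sum(len(t) for t in dtrajs)
        assert max(t.max() for t in new) < len(set(mapping.tolist()))


class TestTRAM:
    def test_single_unbiased_ensemble_equals_reversible_mle(self, discrete_truth):
        traj = dk.sample_chain(discrete_truth, 0, 30_000, seed=11)
        data = [EnsembleData(bias=None, dtrajs=[traj],
                             bias_matrices=[np.zeros((len(traj), 1))])]
        model = tram_estimate(data, lag=1, tol=1e-13)
        ref = mle_reversible(count_transitions([traj], 1, n_states=12))
        assert np.abs(model.T - ref.T).max() < 1e-8
        assert np.abs(model.pi - ref.pi).max() < 1e-7

    def test_truth_recovery_with_biased_ensembles(self, discrete_truth):
        data = _truth_data(discrete_truth, 40_000)
        model = tram_estimate(data, lag=1)
        f_est = model.free_energies()
        f_true = -np.log(discrete_truth.pi_true)
        delta = (f_est - f_est[0]) - (f_true - f_true[0])
        assert np.abs(delta).max() < 0.1

    def test_detailed_balance_of_output(self, discrete_truth):
        data = _truth_data(discrete_truth, 20_000)
        model = tram_estimate(data, lag=1)
        db = model.pi[:, None] * model.T - model.pi[None, :] * model.T.T
        assert np.abs(db).max() < 1e-8

    def test_gauge_invariance_under_constant_bias_shift(self, discrete_truth):
        data = _truth_data(discrete_truth, 15_000)
        shifted = [
            EnsembleData(
                bias=e.bias,
                dtrajs=e.dtrajs,
                bias_matrices=[b + 2.5 for b in e.bias_matrices],
            )
            if e.bias is not None
            else e
            for e in data
        ]
        a = tram_estimate(data, lag=1)
        b = tram_estimate(shifted, lag=1)
        assert np.abs(a.pi - b.pi).max() < 1e-6

    def test_zero_bias_duplicate_pooling(self, discrete_truth):
        """TRAM must treat a zero-bias duplicate ensemble as pooled data."""
        t1 = dk.sample_chain(discrete_truth, 0, 20_000, seed=21)
        t2 = dk.sample_chain(discrete_truth, 0, 20_000, seed=22)
        z = lambda t, k: np.zeros((len(t), k))
        pooled = [EnsembleData(bias=None, dtrajs=[t1, t2],
                               bias_matrices=[z(t1, 1), z(t2, 1)])]
        dup = [
            EnsembleData(bias=None, dtrajs=[t1], bias_matrices=[z(t1, 2)]),
            EnsembleData(bias=dk.BiasSpec(center=(3, 0, 0), k_d=0, k_alpha=0),
                         dtrajs=[t2], bias_matrices=[z(t2, 2)]),
        ]
        a = tram_estimate(pooled, lag=1, tol=1e-11)
        b = tram_estimate(dup, lag=1, tol=1e-11)
        assert np.abs(a.pi - b.pi).max() < 1e-6
        assert np.abs(a.T - b.T).max() < 1e-6

    def test_tightening_tolerance_changes_little(self, discrete_truth):
        data = _truth_data(discrete_truth, 10_000)
        a = tram_estimate(data, lag=1, tol=1e-9)
        b = tram_estimate(data, lag=1, tol=1e-12)
        assert np.abs(a.T - b.T).max() < 1e-7

    def test_unvisited_state_rejected(self):
        traj = np.array([0, 1, 0, 1, 0])
        data = [EnsembleData(bias=None, dtrajs=[traj],
                             bias_matrices=[np.zeros((5, 1))])]
        with pytest.raises(ValueError, match="never visited"):
            tram_estimate(data, lag=1, n_states=3)

    def test_disconnected_fragments_named(self):
        traj = np.array([0, 1, 0, 1, 2, 3, 2, 3])
        traj = np.concatenate([np.tile([0, 1], 10), np.array([]), ]).astype(int)
        t2 = np.tile([2, 3], 10)
        data = [EnsembleData(bias=None, dtrajs=[traj, t2],
                             bias_matrices=[np.zeros((len(traj), 1)),
                                            np.zeros((len(t2), 1))])]
        with pytest.raises(ValueError, match="disconnected"):
            tram_estimate(data, lag=1)

    def test_requires_exactly_one_unbiased(self, discrete_truth):
        traj = dk.sample_chain(discrete_truth, 1, 100, seed=0)
        data = [EnsembleData(bias=dk.BiasSpec(center=(3, 0, 0), k_d=1, k_alpha=1),
                             dtrajs=[traj],
                             bias_matrices=[truthbias(discrete_truth, traj)])]
        with pytest.raises(ValueError, match="unbiased"):
            tram_estimate(data, lag=1)


def truthbias(truth, traj):
    return truth.bias_energies[:1, traj].T


class TestTRAMBootstrap:
    def test_deterministic_and_counts(self, discrete_truth):
        data = _truth_data(discrete_truth, 8_000, split=4)
        a = tram_bootstrap(data, lag=1, n_boot=3, seed=5)
        b = tram_bootstrap(data, lag=1, n_boot=3, seed=5)
        assert len(a) == 3
        for x, y in zip(a, b):
            assert np.array_equal(x.pi, y.pi)

    def test_interval_covers_planted_free_energy_difference(self, discrete_truth):
        data = _truth_data(discrete_truth, 40_000, split=6)
        models = tram_bootstrap(data, lag=1, n_boot=8, seed=1)
        f_true = -np.log(discrete_truth.pi_true)
        df_true = f_true[5] - f_true[0]
        samples = [m.free_energies()[5] - m.free_energies()[0] for m in models]
        lo, hi = np.percentile(samples, [2.5, 97.5])
        width = hi - lo
        assert lo - 0.5 * width <= df_true <= hi + 0.5 * width
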