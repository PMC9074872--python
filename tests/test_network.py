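"""Topology initialization, network simulation, deep rewiring, SynOps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from samsnn import SAMParams, SpikeRaster, forward, init_weights, rewire_step
from samsnn.network import SIGNED_MATRICES


def naive_forward(topology, input_raster, params, n_steps):
    """Unvectorized single-step reference simulator (test oracle)."""
    H, n_in = topology.n_hidden, topology.n_in
    x = np.zeros((n_steps, n_in))
    x[: input_raster.n_steps] = input_raster.to_dense()[:n_steps]
    W, d = topology.weights, topology.delays
    mu, lam = params.mu, params.lam
    V = np.zeros(H); Ve = np.zeros(H); Vi = np.zeros(H); tau = np.zeros(H)
    z = np.zeros(H); ref = np.zeros(H, int)
    zs = np.zeros((n_steps, H), dtype=np.int8)
    for t in range(n_steps):
        I_s = np.zeros(H); I_e = np.zeros(H); I_i = np.zeros(H)
        for j in range(H):
            for i in range(n_in):
                if t - d["W_in_soma"] >= 0:
                    I_s[j] += W["W_in_soma"][i, j] * x[t - d["W_in_soma"], i]
                if t - d["W_in_e"] >= 0:
                    I_e[j] += W["W_in_e"][i, j] * x[t - d["W_in_e"], i]
                if t - d["W_in_i"] >= 0:
                    I_i[j] += W["W_in_i"][i, j] * x[t - d["W_in_i"], i]
            for i in range(H):
                if t - d["W_rec_soma"] >= 0:
                    I_s[j] += W["W_rec_soma"][i, j] * zs[t - d["W_rec_soma"], i]
                if t - d["W_rec_e"] >= 0:
                    I_e[j] += W["W_rec_e"][i, j] * zs[t - d["W_rec_e"], i]
                if t - d["W_rec_i"] >= 0:
                    I_i[j] += W["W_rec_i"][i, j] * zs[t - d["W_rec_i"], i]
        tau = lam * tau + (1 - lam) * z
        gamma = params.tau0 + params.eta * tau
        V = (mu * V + (1 - mu) * params.R_m * I_s
             + (1 - mu) * params.g_exc * (Ve - params.V_exc)
             + (1 - mu) * params.g_inh * (Vi - params.V_inh) - gamma * z)
        Ve = mu * Ve + (1 - mu) * params.R_me * I_e
        Vi = mu * Vi + (1 - mu) * params.R_mi * I_i
        fire = (ref == 0) & (V > gamma)
        z = fire.astype(float)
        ref = np.where(fire, params.n_ref, np.maximum(ref - 1, 0))
        zs[t] = fire
    return zs


class TestSpikeRaster:
    def test_roundtrip_dense_and_file(self, tmp_path, rng):
        dense = (rng.random((40, 7)) < 0.2).astype(np.int8)
        r = SpikeRaster.from_dense(dense)
        assert np.array_equal(r.to_dense(), dense)
        path = tmp_path / "raster.tsv"
        r.save(path)
        r2 = SpikeRaster.load(path)
        assert np.array_equal(r2.to_dense(), dense)
        assert (r2.n_neurons, r2.n_steps) == (7, 40)

    def test_rejects_out_of_range_and_duplicates(self):
        with pytest.raises(ValueError, match="out of range"):
            SpikeRaster(np.array([[10, 0]]), n_neurons=2, n_steps=5)
        with pytest.raises(ValueError, match="duplicate"):
            SpikeRaster(np.array([[1, 0], [1, 0]]), n_neurons=2, n_steps=5)


class TestInitWeights:
    def test_full_connectivity_and_spectral_radius(self, params):
        topo = init_weights(30, 40, 1.0, seed=0, params=params)
        mask = topo.masks["W_rec_e"]
        assert mask.all()
        eig = np.linalg.eigvals(topo.weights["W_rec_soma"])
        assert np.abs(eig).max() < 1.0

    def test_sparse_density_within_binomial_tolerance(self, params):
        conn, n = 0.12, 220
        topo = init_weights(n, n, conn, seed=1, params=params)
        for name in ("W_rec_e", "W_rec_i", "W_in_e"):
            frac = topo.masks[name].mean()
            sigma = np.sqrt(conn * (1 - conn) / topo.masks[name].size)
            assert abs(frac - conn) <= 3 * sigma

    def test_seed_determinism(self, params):
        a = init_weights(10, 12, 0.5, seed=7, params=params)
        b = init_weights(10, 12, 0.5, seed=7, params=params)
        c = init_weights(10, 12, 0.5, seed=8, params=params)
        for name in SIGNED_MATRICES:
            assert np.array_equal(a.weights[name], b.weights[name])
        assert any(not np.array_equal(a.masks[n], c.masks[n]) for n in SIGNED_MATRICES)

    def test_sign_consistency_and_no_self_connections(self, params):
        topo = init_weights(15, 20, 0.8, seed=3, params=params)
        for name in SIGNED_MATRICES:
            W = topo.weights[name]
            signs = topo.sign_of(name)
            assert np.all(W * signs >= 0)
        assert np.all(np.diag(topo.weights["W_rec_soma"]) == 0)

    def test_input_to_soma_disabled_by_default(self, params):
        topo = init_weights(15, 20, 1.0, seed=3, params=params)
        assert not topo.masks["W_in_soma"].any()

    def test_connectivity_validation(self, params):
        with pytest.raises(ValueError, match="connectivity"):
            init_weights(5, 5, 0.0, seed=0, params=params)


class TestForward:
    def test_empty_input_stays_silent(self, params):
        topo = init_weights(8, 10, 1.0, seed=0, params=params, n_out=2)
        empty = SpikeRaster(np.empty((0, 2), dtype=int), 8, 50)
        hidden, y, gamma, synops = forward(topo, empty, params)
        assert hidden.n_spikes == 0
        assert np.all(y == 0)
        assert synops == 0

    def test_single_spike_first_drive_after_delay(self, params):
        topo = init_weights(1, 5, 1.0, seed=0, params=params)
        # make the excitatory input pathway strong enough to elicit a response
        topo.weights["W_in_e"] = np.abs(topo.weights["W_in_e"]) * 0 + 5.0
        raster = SpikeRaster(np.array([[0, 0]]), 1, 40)
        hidden, _, _, _ = forward(topo, raster, params)
        d = topo.delays["W_in_e"]
        assert d == 5
        first = hidden.events[:, 0].min()
        # spike at step 0 reaches the dendrite at t=d; the soma reads the
        # dendritic potential one step later, so the earliest response is d+1
        assert first == d + 1

    def test_matches_naive_reference(self, params, rng):
        topo = init_weights(6, 20, 0.7, seed=11, params=params, n_out=3)
        for name in topo.weights:  # scale up so the network actually spikes
            topo.weights[name] = topo.weights[name] * 4.0
        raster = SpikeRaster.from_dense((rng.random((100, 6)) < 0.3).astype(np.int8))
        hidden, _, _, _ = forward(topo, raster, params, n_steps=100)
        ref = naive_forward(topo, raster, params, 100)
        assert ref.sum() > 0
        assert np.array_equal(hidden.to_dense(), ref)

    def test_dendritic_drive_linear_in_input_superposition(self, params, rng):
        # with spiking disabled (huge tau0) the somatic potential superposes:
        # V(A union B) = V(A) + V(B) for disjoint input rasters
        from samsnn.learning import forward_pass

        quiet = params.with_(tau0=1e6)
        topo = init_weights(6, 8, 1.0, seed=2, params=quiet)
        a = (rng.random((60, 6)) < 0.3).astype(float)
        b = ((rng.random((60, 6)) < 0.3) & (a == 0)).astype(float)
        va = forward_pass(topo, quiet, a[None])["V"]
        vb = forward_pass(topo, quiet, b[None])["V"]
        vab = forward_pass(topo, quiet, (a + b)[None])["V"]
        assert np.allclose(va + vb, vab, atol=1e-12)

    def test_synops_matches_brute_force(self, params, rng):
        topo = init_weights(6, 12, 0.4, seed=5, params=params, n_out=2)
        for name in topo.weights:
            topo.weights[name] = topo.weights[name] * 4.0
        dense_in = (rng.random((80, 6)) < 0.4).astype(np.int8)
        hidden, _, _, synops = forward(topo, SpikeRaster.from_dense(dense_in), params)
        expected = 0
        in_counts = dense_in.sum(axis=0)
        hid_counts = hidden.to_dense().sum(axis=0)
        for i in range(6):
            fan = sum(topo.masks[k][i].sum() for k in ("W_in_soma", "W_in_e", "W_in_i"))
            expected += int(in_counts[i]) * int(fan)
        for j in range(12):
            fan = sum(topo.masks[k][j].sum() for k in ("W_rec_soma", "W_rec_e", "W_rec_i")) + 2
            expected += int(hid_counts[j]) * int(fan)
        assert synops == expected

    def test_shape_mismatch_rejected(self, params):
        topo = init_weights(8, 10, 1.0, seed=0, params=params)
        with pytest.raises(ValueError, match="channels"):
            forward(topo, SpikeRaster(np.empty((0, 2), int), 5, 50), params)


class TestRewiring:
    def test_zero_gradients_zero_l1_is_identity(self, params):
        topo = init_weights(10, 10, 0.5, seed=0, params=params)
        new = rewire_step(topo, {}, l1=0.0, seed=0)
        for name in SIGNED_MATRICES:
            assert np.array_equal(new.weights[name], topo.weights[name])
            assert np.array_equal(new.masks[name], topo.masks[name])

    def test_sign_crossing_becomes_dormant_and_count_conserved(self, params):
        topo = init_weights(10, 10, 0.5, seed=0, params=params)
        before = topo.active_counts()
        # push every active weight of one pathway past zero
        W = topo.weights["W_rec_e"]
        grad = {"W_rec_e": -2.0 * W}
        new = rewire_step(topo, grad, l1=0.0, seed=1)
        after = new.active_counts()
        assert after == before
        # the replacement synapses are fresh (tiny magnitude), not the old ones
        moved = (new.masks["W_rec_e"] != topo.masks["W_rec_e"]).sum()
        assert moved > 0

    def test_long_random_walk_never_violates_signs(self, params, rng):
        topo = init_weights(8, 8, 0.5, seed=0, params=params)
        for step in range(300):
            grads = {name: rng.normal(0, 0.02, topo.weights[name].shape)
                     for name in SIGNED_MATRICES}
            topo = rewire_step(topo, grads, l1=1e-4, rng=rng)
            for name in SIGNED_MATRICES:
                signs = topo.sign_of(name)
                W = topo.weights[name]
                assert np.all(W[topo.masks[name]] * np.broadcast_to(signs, W.shape)[topo.masks[name]] > 0)
                assert np.all(W[~topo.masks[name]] == 0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_active_count_invariant_under_random_updates(self, seed):
        params = SAMParams()
        topo = init_weights(6, 6, 0.5, seed=0, params=params)
        before = topo.active_counts()
        g = np.random.default_rng(seed)
        grads = {name: g.normal(0, 0.05, topo.weights[name].shape) for name in SIGNED_MATRICES}
        new = rewire_step(topo, grads, l1=0.001, rng=g)
        assert new.active_counts() == before

    def test_rejects_negative_l1(self, params):
        topo = init_weights(5, 5, 0.5, seed=0, params=params)
        with pytest.raises(ValueError):
            rewire_step(topo, {}, l1=-0.1)
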