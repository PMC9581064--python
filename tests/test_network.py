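import numpy as np
import pytest

from consdeepsignaling import (ModelConfig, PathwayMembership,
                               build_gene_feature_mask, build_gene_pathway_mask,
                               build_model, init_model, load_checkpoint,
                               save_checkpoint, train, CONSDEEP_SCHEDULE)
from consdeepsignaling.network import (Activation, Linear, Parameter, Sequential,
                                       build_dnn_baseline, build_pasnet_baseline,
                                       build_pathdnn_baseline)


def random_masks(rng, K, n, s):
    gf = build_gene_feature_mask(K, n)
    # random gene->pathway membership with every pathway non-empty
    values = (rng.random((n, s)) < 0.5).astype(float)
    for t in range(s):
        if values[:, t].sum() == 0:
            values[rng.integers(n), t] = 1.0
    membership = PathwayMembership(
        {f"p{t}": {f"g{j+1}" for j in range(n) if values[j, t]} for t in range(s)},
        [f"p{t}" for t in range(s)])
    gp = build_gene_pathway_mask(membership, [f"g{j+1}" for j in range(n)])
    return gf, gp


def brute_force_forward(model, x):
    """Independent oracle: explicit per-gene / per-pathway / per-unit loops."""
    cfg = model.config
    K, n, s = cfg.K, cfg.n, cfg.s
    lin_xg, act1, lin_gp, act2 = model.tiers.layers

    def act(v):
        if cfg.gene_pathway_activation == "relu":
            return max(v, 0.0)
        return v

    g = []
    for j in range(n):
        total = 0.0
        for m in range(K):
            i = K * j + m
            total += lin_xg.W.mask[i, j] * lin_xg.W.value[i, j] * x[i]
        if lin_xg.b is not None:
            total += lin_xg.b.value[j]
        g.append(act(total))
    p = []
    for t in range(s):
        total = 0.0
        for j in range(n):
            total += lin_gp.W.mask[j, t] * lin_gp.W.value[j, t] * g[j]
        if lin_gp.b is not None:
            total += lin_gp.b.value[t]
        p.append(act(total))
    h = p
    linears = [l for l in model.head.layers if isinstance(l, Linear)]
    for li, lin in enumerate(linears):
        out = []
        for c in range(lin.W.value.shape[1]):
            total = lin.b.value[c]
            for r in range(lin.W.value.shape[0]):
                total += lin.W.value[r, c] * h[r]
            if li < len(linears) - 1:  # ReLU on all but the linear output
                total = max(total, 0.0)
            out.append(total)
        h = out
    assert len(h) == 1
    return h[0]


class TestForward:
    def test_hand_computed_two_gene_example(self):
        # K=1, n=2, s=1; all unmasked weights 1, linear tiers, identity head:
        # x=[2,3] -> g=[2,3] -> p=[5] -> prediction 5
        gf = build_gene_feature_mask(1, 2)
        membership = PathwayMembership({"P": {"g1", "g2"}}, ["P"])
        gp = build_gene_pathway_mask(membership, ["g1", "g2"])
        model = init_model(ModelConfig(K=1, n=2, s=1, head_sizes=(1,), seed=0), gf, gp)
        model.tiers.layers[0].W.value = gf.values.copy()
        model.tiers.layers[2].W.value = gp.values.copy()
        # head: s=1 -> 1 ReLU unit -> 1 output, weights 1, biases 0
        for layer in model.head.layers:
            if isinstance(layer, Linear):
                layer.W.value = np.ones_like(layer.W.value)
                layer.b.value = np.zeros_like(layer.b.value)
        assert model.forward(np.array([2.0, 3.0])) == pytest.approx(5.0)

    def test_zero_input_linear_tiers(self):
        rng = np.random.default_rng(0)
        gf, gp = random_masks(rng, 2, 4, 2)
        model = init_model(ModelConfig(K=2, n=4, s=2, head_sizes=(3,), seed=1), gf, gp)
        # g = 0 and p = 0, so the prediction equals head(0)
        zero_pred = model.forward(np.zeros(8))
        head_at_zero = model.head.forward(np.zeros((1, 2)))[0, 0]
        assert zero_pred == pytest.approx(head_at_zero)

    @pytest.mark.parametrize("activation", ["linear", "relu"])
    def test_matches_brute_force_oracle(self, activation):
        rng = np.random.default_rng(42)
        for trial in range(100):
            K = int(rng.integers(1, 4))
            n = int(rng.integers(1, 11))
            s = int(rng.integers(1, 5))
            gf, gp = random_masks(rng, K, n, s)
            cfg = ModelConfig(K=K, n=n, s=s, head_sizes=(5, 3),
                              gene_pathway_activation=activation,
                              use_bias_masked_layers=bool(rng.integers(2)),
                              seed=int(rng.integers(1 << 20)))
            model = init_model(cfg, gf, gp)
            x = rng.normal(size=K * n)
            expected = brute_force_forward(model, x)
            got = model.forward(x)
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        gf, gp = random_masks(rng, 2, 3, 2)
        model = init_model(ModelConfig(K=2, n=3, s=2, seed=0), gf, gp)
        with pytest.raises(ValueError):
            model.forward(np.zeros(5))


class TestInit:
    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(3)
        gf, gp = random_masks(rng, 3, 5, 2)
        cfg = ModelConfig(K=3, n=5, s=2, seed=99)
        a, b = init_model(cfg, gf, gp), init_model(cfg, gf, gp)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_masked_positions_zero_after_init(self):
        rng = np.random.default_rng(4)
        gf, gp = random_masks(rng, 3, 6, 3)
        model = init_model(ModelConfig(K=3, n=6, s=3, seed=0), gf, gp)
        for lin in (model.tiers.layers[0], model.tiers.layers[2]):
            assert np.all(lin.W.value[lin.W.mask == 0] == 0)

    def test_wrong_mask_shape_rejected(self):
        rng = np.random.default_rng(5)
        gf, gp = random_masks(rng, 2, 4, 2)
        with pytest.raises(ValueError):
            init_model(ModelConfig(K=3, n=4, s=2, seed=0), gf, gp)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(K=3, n=4, s=2, head_sizes=())
        with pytest.raises(ValueError):
            ModelConfig(K=0, n=4, s=2)


class TestLocality:
    def test_gene_perturbation_is_local_at_gene_tier(self):
        rng = np.random.default_rng(6)
        K, n, s = 3, 8, 3
        gf, gp = random_masks(rng, K, n, s)
        model = init_model(ModelConfig(K=K, n=n, s=s, seed=0), gf, gp)
        x = rng.normal(size=K * n)
        g0 = model.tiers.layers[0].forward(x[None, :])[0]
        j = 4
        x2 = x.copy()
        x2[K * j:K * (j + 1)] += rng.normal(size=K)
        g1 = model.tiers.layers[0].forward(x2[None, :])[0]
        changed = np.flatnonzero(g0 != g1)
        assert set(changed) <= {j}

    def test_pathway_unaffected_by_non_member_genes(self):
        rng = np.random.default_rng(7)
        K, n, s = 2, 8, 3
        gf, gp = random_masks(rng, K, n, s)
        model = init_model(ModelConfig(K=K, n=n, s=s, seed=1), gf, gp)
        t = 0
        members = np.flatnonzero(gp.values[:, t])
        outsiders = [j for j in range(n) if j not in members]
        if not outsiders:
            pytest.skip("mask draw left pathway 0 with all genes as members")
        x = rng.normal(size=K * n)
        p0 = model.pathway_activations(x[None, :])[0, t]
        x2 = x.copy()
        for j in outsiders:
            x2[K * j:K * (j + 1)] += rng.normal(size=K)
        p1 = model.pathway_activations(x2[None, :])[0, t]
        assert p0 == pytest.approx(p1, abs=1e-12)


class TestGradientMasking:
    def test_masked_weights_and_gradients_stay_exactly_zero(self):
        rng = np.random.default_rng(8)
        K, n, s = 3, 10, 4
        gf, gp = random_masks(rng, K, n, s)
        model = init_model(ModelConfig(K=K, n=n, s=s, head_sizes=(8, 4), seed=0),
                           gf, gp)
        X = rng.normal(size=(64, K * n))
        y = rng.random(64)
        masked = [(model.tiers.layers[0].W, gf.values == 0),
                  (model.tiers.layers[2].W, gp.values == 0)]

        audits = []

        def audit(params):
            for p, zero in masked:
                audits.append(np.all(p.grad[zero] == 0.0))

        train(model, X, y, CONSDEEP_SCHEDULE, epochs=13, batch_size=16, seed=0,
              grad_callback=audit)
        assert audits and all(audits)
        for p, zero in masked:
            assert np.all(p.value[zero] == 0.0)


class TestBaselines:
    def test_dnn_is_dense_and_runs(self):
        cfg = ModelConfig(K=3, n=6, s=2, seed=0)
        model = build_dnn_baseline(cfg)
        assert model.tiers is None
        assert np.isfinite(model.forward(np.random.default_rng(0).normal(size=18)))

    def test_pathdnn_uses_expression_and_target_only(self):
        rng = np.random.default_rng(9)
        gf, gp = random_masks(rng, 3, 6, 2)
        model = build_pathdnn_baseline(ModelConfig(K=3, n=6, s=2, seed=0), gp)
        x = rng.normal(size=18)
        x_cnv = x.copy()
        x_cnv[1::3] += 100.0  # perturb CNV columns only
        assert model.forward(x) == pytest.approx(model.forward(x_cnv))

    def test_pasnet_uses_expression_only_and_has_l2(self):
        rng = np.random.default_rng(10)
        gf, gp = random_masks(rng, 3, 6, 2)
        model = build_pasnet_baseline(ModelConfig(K=3, n=6, s=2, seed=0), gp)
        x = rng.normal(size=18)
        x2 = x.copy()
        x2[1::3] += 5.0
        x2[2::3] = 1.0 - x2[2::3]
        assert model.forward(x) == pytest.approx(model.forward(x2))
        assert any(p.l2 == 0.01 for p in model.params())

    def test_builder_dispatch(self):
        rng = np.random.default_rng(11)
        gf, gp = random_masks(rng, 3, 6, 2)
        cfg = ModelConfig(K=3, n=6, s=2, seed=0)
        for kind in ("consdeepsignaling", "dnn", "pathdnn", "pasnet"):
            model = build_model(kind, cfg, gene_feature_mask=gf, gene_pathway_mask=gp)
            assert model.kind == kind
        with pytest.raises(ValueError):
            build_model("mystery", cfg)


class TestCheckpoint:
    @pytest.mark.parametrize("kind", ["consdeepsignaling", "pasnet"])
    def test_round_trip_is_bitwise_identical(self, tmp_path, kind):
        rng = np.random.default_rng(12)
        gf, gp = random_masks(rng, 3, 8, 3)
        cfg = ModelConfig(K=3, n=8, s=3, head_sizes=(6, 4), seed=5)
        model = build_model(kind, cfg, gene_feature_mask=gf, gene_pathway_mask=gp)
        X = rng.normal(size=(32, 24))
        train(model, X, rng.random(32), CONSDEEP_SCHEDULE, epochs=3,
              batch_size=8, seed=0)
        path = tmp_path / "model.zip"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        Xt = rng.normal(size=(10, 24))
        np.testing.assert_array_equal(model.predict(Xt), back.predict(Xt))
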