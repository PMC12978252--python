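"""Stability model: encoding, instance building, forward oracle, training."""

import numpy as np
import pandas as pd
import pytest

from greyhound.model import (
    GreyHound,
    ModelConfig,
    build_instances,
    one_hot_encode,
)
from greyhound.simulate import SimConfig, simulate_dataset
from greyhound.vae import RBPVAE, VAEConfig


class TestOneHot:
    def test_acgt_is_channel_identity(self):
        oh = one_hot_encode("ACGT", max_length=4)
        assert np.array_equal(oh.matrix, np.eye(4))

    def test_u_maps_to_t_channel(self):
        oh = one_hot_encode("U", max_length=1)
        assert oh.matrix[3, 0] == 1.0 and oh.matrix[:3, 0].sum() == 0

    def test_ambiguous_base_is_zero_column(self):
        oh = one_hot_encode("N", max_length=1)
        assert oh.matrix.sum() == 0.0

    def test_padding_arithmetic(self):
        seq = "ACGT" * 128  # 512 nt
        oh = one_hot_encode(seq, max_length=4096)
        assert oh.matrix.shape == (4, 4096)
        assert oh.matrix[:, 512:].sum() == 0.0
        assert (oh.matrix[:, :512].sum(axis=0) == 1).all()
        assert oh.mask.sum() == 512

    def test_real_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=77))
        oh = one_hot_encode(seq, max_length=100)
        assert (oh.matrix[:, :77].sum(axis=0) == 1).all()

    def test_same_sequence_encodes_identically(self):
        a = one_hot_encode("ACGGTTAC", 20)
        b = one_hot_encode("ACGGTTAC", 20)
        assert np.array_equal(a.matrix, b.matrix)

    def test_errors(self):
        with pytest.raises(ValueError):
            one_hot_encode("ACGT" * 10, max_length=8)  # too long: excluded upstream
        with pytest.raises(ValueError):
            one_hot_encode("ACXT", max_length=10)  # illegal character
        with pytest.raises(ValueError):
            one_hot_encode("", max_length=10)


@pytest.fixture(scope="module")
def instances_fixture():
    cfg = SimConfig(n_genes=100, length_range=(60, 120), n_rbps=12,
                    latent_rank=3, seed=21)
    truth, _ = simulate_dataset(cfg, depth=100)
    return truth


class TestBuildInstances:
    def test_complete_matrix_split_sizes(self, instances_fixture):
        truth = instances_fixture
        inst = build_instances(
            truth.sequences, truth.true_log_decay, truth.rbp_matrix,
            seed=0, max_length=120, min_length=1,
        )
        assert len(inst) == 100 * 6
        assert len(inst.indices("train")) == 480
        assert len(inst.indices("val")) == 30
        assert len(inst.indices("test")) == 90

    def test_gene_disjoint_mode(self, instances_fixture):
        truth = instances_fixture
        inst = build_instances(
            truth.sequences, truth.true_log_decay, truth.rbp_matrix,
            seed=0, mode="gene_holdout", max_length=120, min_length=1,
        )
        by_split = {
            s: {inst.genes[g] for g in inst.gene_idx[inst.indices(s)]}
            for s in ("train", "val", "test")
        }
        assert not (by_split["train"] & by_split["test"])
        assert not (by_split["train"] & by_split["val"])

    def test_loo_mode_test_is_single_cell(self, instances_fixture):
        truth = instances_fixture
        held = truth.cells[2]
        inst = build_instances(
            truth.sequences, truth.true_log_decay, truth.rbp_matrix,
            seed=0, mode=f"loo:{held}", max_length=120, min_length=1,
        )
        test_cells = {inst.cells[c] for c in inst.cell_idx[inst.indices("test")]}
        assert test_cells == {held}
        train_cells = {inst.cells[c] for c in inst.cell_idx[inst.indices("train")]}
        assert held not in train_cells

    def test_masked_entries_skipped_and_min_cells(self, instances_fixture):
        truth = instances_fixture
        decay = truth.true_log_decay.copy()
        decay.iloc[0, :3] = np.nan  # gene 0 keeps 3 of 6 cells
        inst = build_instances(
            truth.sequences, decay, truth.rbp_matrix,
            seed=0, max_length=120, min_length=1, min_cells=4,
        )
        g0 = truth.true_log_decay.index[0]
        assert g0 not in inst.genes
        assert g0 in inst.excluded

    def test_out_of_length_genes_excluded_with_reason(self, instances_fixture):
        truth = instances_fixture
        inst = build_instances(
            truth.sequences, truth.true_log_decay, truth.rbp_matrix,
            seed=0, max_length=120, min_length=100,
        )
        assert all("length" in v for v in inst.excluded.values())
        assert len(inst.genes) + len(inst.excluded) == 100


def _manual_forward(model, X, P):
    """Independent layer-by-layer recomputation of the eval-mode forward."""
    cfg = model.config

    def conv1d(x, W, b, dilation=1):
        n, c, L = x.shape
        c_out, _, k = W.shape
        span = dilation * (k - 1)
        left = span // 2
        xp = np.pad(x, ((0, 0), (0, 0), (left, span - left)))
        out = np.zeros((n, c_out, L))
        for o in range(c_out):
            for i in range(k):
                for ch in range(c):
                    out[:, o, :] += W[o, ch, i] * xp[:, ch, i * dilation : i * dilation + L]
            out[:, o, :] += b[o]
        return out

    def lrelu(x, alpha=0.1):
        return np.where(x > 0, x, alpha * x)

    def bn_eval(x, bn):
        inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
        return (
            bn.gamma.value[None, :, None]
            * (x - bn.running_mean[None, :, None])
            * inv[None, :, None]
            + bn.beta.value[None, :, None]
        )

    def maxpool(x, p):
        n, c, L = x.shape
        lo = L // p
        return x[:, :, : lo * p].reshape(n, c, lo, p).max(axis=3)

    from greyhound import nn as nnmod

    h = X.copy()
    layers = iter(model.seq_trunk.layers)
    for filters, kernel, pool, _drop in cfg.conv_blocks:
        conv = next(layers)
        h = conv1d(h, conv.W.value, conv.b.value)
        next(layers)  # LeakyReLU
        h = lrelu(h)
        bn = next(layers)
        h = bn_eval(h, bn)
        next(layers)  # MaxPool
        h = maxpool(h, pool)
        next(layers)  # Dropout (identity in eval)
    res_block = next(layers)
    skip = h if res_block.project is None else conv1d(
        h, res_block.project.W.value, res_block.project.b.value
    )
    acc = skip.copy()
    for branch, d in zip(res_block.branches, cfg.dilations):
        acc = acc + conv1d(h, branch.W.value, branch.b.value, dilation=d)
    h = lrelu(acc)
    feats = h.reshape(h.shape[0], -1)

    hp = lrelu(P @ model.enc_hidden.W.value + model.enc_hidden.b.value)
    mu = hp @ model.enc_mu.W.value + model.enc_mu.b.value

    z = np.concatenate([feats, mu], axis=1)
    it = iter(model.integration.layers)
    for i, w in enumerate(list(cfg.integration) + [1]):
        dense = next(it)
        z = z @ dense.W.value + dense.b.value
        if i < len(cfg.integration):
            next(it)
            z = lrelu(z)
    return z[:, 0]


@pytest.fixture(scope="module")
def tiny_model(instances_fixture):
    truth = instances_fixture
    vae = RBPVAE.from_dataframe(
        truth.rbp_matrix,
        VAEConfig(hidden_size=10, latent_size=4, epochs=4, augment_draws=10, seed=1),
    ).fit()
    cfg = ModelConfig(
        max_length=120, min_length=1,
        conv_blocks=((6, 5, 4, 0.1), (6, 3, 4, 0.1)),
        dilated_filters=8, dilated_kernel=3, integration=(10,),
        latent_size=4, stage1_epochs=2, stage2_epochs=1, seed=2,
    )
    inst = build_instances(truth.sequences, truth.true_log_decay, truth.rbp_matrix,
                           seed=2, max_length=120, min_length=1)
    return GreyHound(inst, vae, cfg), vae


class TestForward:
    def test_matches_independent_manual_recomputation(self, tiny_model):
        model, _ = tiny_model
        inst = model.instances
        X = inst.X[:5]
        P = inst.profiles[inst.cell_idx[:5]]
        # exercise batch-norm running stats first
        model.forward(inst.X[5:25], inst.profiles[inst.cell_idx[5:25]], train=True)
        got = model.forward(X, P, train=False)
        manual = _manual_forward(model, X, P)
        assert np.allclose(got, manual, atol=1e-5)

    def test_zero_weights_give_zero_output(self, tiny_model):
        import copy

        model, _ = tiny_model
        clone = copy.deepcopy(model)
        for p in clone.params():
            p.value[...] = 0.0
        for bn in clone._bn_layers():
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0
            bn.beta.value[...] = 0.0
            bn.gamma.value[...] = 0.0
        inst = clone.instances
        out = clone.forward(inst.X[:3], inst.profiles[:3], train=False)
        assert np.allclose(out, 0.0)

    def test_eval_mode_bit_identical(self, tiny_model):
        model, _ = tiny_model
        inst = model.instances
        X, P = inst.X[:4], inst.profiles[inst.cell_idx[:4]]
        a = model.forward(X, P, train=False)
        b = model.forward(X, P, train=False)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_raises(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 120)), np.zeros((1, 12)))


class TestTrainingProtocol:
    @pytest.fixture(scope="class")
    def trained(self, instances_fixture):
        truth = instances_fixture
        vae = RBPVAE.from_dataframe(
            truth.rbp_matrix,
            VAEConfig(hidden_size=10, latent_size=4, epochs=4, augment_draws=10, seed=3),
        ).fit()
        cfg = ModelConfig(
            max_length=120, min_length=1,
            conv_blocks=((6, 5, 4, 0.1), (6, 3, 4, 0.1)),
            dilated_filters=8, dilated_kernel=3, integration=(10,),
            latent_size=4, stage1_epochs=3, stage2_epochs=2,
            grad_clip_norm=5.0, seed=4,
        )
        inst = build_instances(truth.sequences, truth.true_log_decay, truth.rbp_matrix,
                               seed=4, max_length=120, min_length=1)
        model = GreyHound(inst, vae, cfg)
        encoder_before = [p.value.copy() for p in model.encoder_params()]
        res = model.fit()
        return model, res, vae, encoder_before

    def test_source_vae_never_mutated(self, trained):
        model, _res, vae, _ = trained
        for p_model, p_vae in zip(model.encoder_params(), vae.model.encoder_params()[:4]):
            pass  # transfer copies: mutating the model must not touch the VAE
        # the VAE's own weights still reproduce its reconstructions
        assert all(np.isfinite(p.value).all() for p in vae.model.params())

    def test_stage1_only_leaves_encoder_frozen(self, instances_fixture):
        truth = instances_fixture
        vae = RBPVAE.from_dataframe(
            truth.rbp_matrix,
            VAEConfig(hidden_size=10, latent_size=4, epochs=3, augment_draws=10, seed=5),
        ).fit()
        cfg = ModelConfig(
            max_length=120, min_length=1,
            conv_blocks=((6, 5, 4, 0.1), (6, 3, 4, 0.1)),
            dilated_filters=8, dilated_kernel=3, integration=(10,),
            latent_size=4, stage1_epochs=2, stage2_epochs=0, seed=6,
        )
        inst = build_instances(truth.sequences, truth.true_log_decay, truth.rbp_matrix,
                               seed=6, max_length=120, min_length=1)
        model = GreyHound(inst, vae, cfg)
        before = [p.value.copy() for p in model.encoder_params()]
        model.fit()
        for b, p in zip(before, model.encoder_params()):
            assert np.array_equal(b, p.value), "encoder changed during frozen stage"

    def test_stage2_updates_encoder(self, instances_fixture):
        truth = instances_fixture
        vae = RBPVAE.from_dataframe(
            truth.rbp_matrix,
            VAEConfig(hidden_size=10, latent_size=4, epochs=2, augment_draws=10, seed=9),
        ).fit()
        cfg = ModelConfig(
            max_length=120, min_length=1,
            conv_blocks=((6, 5, 4, 0.1), (6, 3, 4, 0.1)),
            dilated_filters=8, dilated_kernel=3, integration=(10,),
            latent_size=4, stage1_epochs=0, stage2_epochs=2, seed=10,
        )
        inst = build_instances(truth.sequences, truth.true_log_decay, truth.rbp_matrix,
                               seed=10, max_length=120, min_length=1)
        model = GreyHound(inst, vae, cfg)
        before = [p.value.copy() for p in model.encoder_params()]
        model.fit()
        changed = any(
            not np.array_equal(b, p.value)
            for b, p in zip(before, model.encoder_params())
        )
        assert changed, "fine-tuning stage should update the encoder"

    def test_gradient_clipping_enforced_every_step(self, trained):
        _model, res, _vae, _ = trained
        post = res.grad_norms[:, 1]
        assert (post <= 5.0 + 1e-6).all()

    def test_history_and_best_snapshot(self, trained):
        _model, res, _vae, _ = trained
        assert len(res.history) == 5
        assert set(res.history["stage"]) == {1, 2}
        assert res.best_val_pearson == pytest.approx(res.history["val_pearson"].max())

    def test_evaluate_identity_and_sign(self, trained):
        model, res, _vae, _ = trained
        table = res.predictions("test")
        from scipy.stats import pearsonr

        r_direct, _ = pearsonr(table["y_true"], table["y_pred"])
        assert res.evaluate("test")["pearson"] == pytest.approx(r_direct)
        # predictions == targets -> r = 1; negated -> -1
        fake = table.assign(y_pred=table["y_true"])
        assert pearsonr(fake["y_true"], fake["y_pred"])[0] == pytest.approx(1.0)
        fake = table.assign(y_pred=-table["y_true"])
        assert pearsonr(fake["y_true"], fake["y_pred"])[0] == pytest.approx(-1.0)

    def test_untrained_model_permutation_band_covers_zero(self, instances_fixture):
        truth = instances_fixture
        vae = RBPVAE.from_dataframe(
            truth.rbp_matrix,
            VAEConfig(hidden_size=10, latent_size=4, epochs=2, augment_draws=10, seed=7),
        ).fit()
        cfg = ModelConfig(
            max_length=120, min_length=1,
            conv_blocks=((6, 5, 4, 0.1), (6, 3, 4, 0.1)),
            dilated_filters=8, dilated_kernel=3, integration=(10,),
            latent_size=4, stage1_epochs=0, stage2_epochs=0, seed=8,
        )
        inst = build_instances(truth.sequences, truth.true_log_decay, truth.rbp_matrix,
                               seed=8, max_length=120, min_length=1)
        model = GreyHound(inst, vae, cfg)
        idx = inst.indices("test")
        X, P, y = model._batch(idx)
        pred = model.forward(X, P, train=False)
        r = np.corrcoef(pred, y)[0, 1]
        rng = np.random.default_rng(0)
        perm_rs = []
        for _ in range(200):
            perm_rs.append(np.corrcoef(pred, rng.permutation(y))[0, 1])
        lo, hi = np.quantile(perm_rs, [0.025, 0.975])
        assert lo <= 0 <= hi
        assert lo - 0.15 <= r <= hi + 0.15  # untrained predictions look like noise
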