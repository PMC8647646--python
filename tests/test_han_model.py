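import dataclasses

import numpy as np
import pytest

from hanppis import autodiff as ad
from hanppis.autodiff import Tensor
from hanppis.config import TrainConfig
from hanppis.fragmenter import DatasetSplit, extract_window
from hanppis.han_model import (
    adam_step,
    attention_pool,
    bigru_encode,
    forward,
    forward_batch,
    init_params,
    predict,
    project_embedding,
    train,
    weighted_bce_loss,
    load_checkpoint,
    save_checkpoint,
)
from hanppis.io_features import raw_width
from hanppis.synthetic import synth_feature_source


def _fragment(cfg, center=3, L=9, seed=0, label=1):
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(L, raw_width(cfg.embed_dim))).astype(np.float32)
    labels = np.zeros(L, dtype=np.int8)
    labels[center] = label
    return extract_window(feats, "ACDEFGHIK"[:L], labels, center, cfg.window, "p")


# -- building blocks ---------------------------------------------------------


def test_project_embedding_shapes_and_zero_params():
    W = Tensor(np.zeros((5, 3)))
    b = Tensor(np.zeros(3))
    out = project_embedding(np.ones((4, 5)), W, b)
    assert out.shape == (4, 3)
    assert (out.data == 0).all()


def test_project_embedding_identity_passthrough():
    W = Tensor(np.eye(4))
    b = Tensor(np.zeros(4))
    e = np.abs(np.random.default_rng(0).normal(size=(2, 4)))
    np.testing.assert_allclose(project_embedding(e, W, b).data, e)


def test_project_embedding_shape_mismatch():
    with pytest.raises(ValueError):
        project_embedding(np.ones((2, 6)), Tensor(np.zeros((5, 3))), Tensor(np.zeros(3)))


def test_fused_width_matches_block_arithmetic():
    assert TrainConfig().fused_width == 101
    assert TrainConfig(projection=10).fused_width == 61
    assert TrainConfig(dropped_blocks=("one_hot",)).fused_width == 81
    assert TrainConfig(dropped_blocks=("embedding",)).fused_width == 51
    assert TrainConfig(dropped_blocks=("hydropathy",)).fused_width == 100


def test_bigru_zero_params_zero_output(tiny_config):
    params = init_params(tiny_config, seed=0)
    for name, t in params.tensors.items():
        t.data = np.zeros_like(t.data)
    X = np.random.default_rng(0).normal(size=(1, tiny_config.fused_width))
    H = bigru_encode(X.reshape(1, 1, -1), params, level="res")
    assert H.shape == (1, 1, 2 * tiny_config.hidden)
    np.testing.assert_allclose(H.data, 0.0)


def test_bigru_output_width(tiny_config):
    params = init_params(tiny_config, seed=0)
    X = np.random.default_rng(0).normal(size=(2, 3, tiny_config.fused_width))
    H = bigru_encode(X, params, level="res")
    assert H.shape == (2, 3, 2 * tiny_config.hidden)


def test_bigru_reversal_swaps_directional_halves(tiny_config):
    u = tiny_config.hidden
    params = init_params(tiny_config, seed=0)
    # tie the two directions so reversal symmetry is exact
    for pname in ("Wzr", "Uzr", "bzr", "Wc", "Uc", "bc"):
        params.tensors[f"res_bw_{pname}"].data = params[f"res_fw_{pname}"].data.copy()
    X = np.random.default_rng(1).normal(size=(1, 5, tiny_config.fused_width))
    H = bigru_encode(X, params, level="res").data[0]
    H_rev = bigru_encode(X[:, ::-1].copy(), params, level="res").data[0]
    np.testing.assert_allclose(H[:, :u], H_rev[::-1, u:], atol=1e-12)
    np.testing.assert_allclose(H[:, u:], H_rev[::-1, :u], atol=1e-12)


def test_attention_singleton_weight_is_one(tiny_config):
    params = init_params(tiny_config, seed=0)
    H = np.random.default_rng(0).normal(size=(1, 2 * tiny_config.hidden))
    v, alpha = attention_pool(H, params["res_att_W"], params["res_att_b"],
                              params["res_att_u"])
    np.testing.assert_allclose(alpha.data, [1.0])
    np.testing.assert_allclose(v.data, H[0])


def test_attention_identical_rows_uniform(tiny_config):
    params = init_params(tiny_config, seed=0)
    row = np.random.default_rng(0).normal(size=2 * tiny_config.hidden)
    H = np.tile(row, (4, 1))
    _, alpha = attention_pool(H, params["res_att_W"], params["res_att_b"],
                              params["res_att_u"])
    np.testing.assert_allclose(alpha.data, 0.25)


def test_attention_normalises_and_masks(tiny_config):
    params = init_params(tiny_config, seed=0)
    H = np.random.default_rng(2).normal(size=(3, 5, 2 * tiny_config.hidden))
    mask = np.array([[1, 1, 1, 0, 0], [1, 0, 1, 0, 1], [1, 1, 1, 1, 1]])
    _, alpha = attention_pool(H, params["res_att_W"], params["res_att_b"],
                              params["res_att_u"], mask)
    np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-12)
    assert (alpha.data[mask == 0] == 0).all()
    assert (alpha.data >= 0).all()


def test_attention_permutation_equivariance(tiny_config):
    """Permuting rows permutes weights identically (no recurrence involved)."""
    params = init_params(tiny_config, seed=0)
    H = np.random.default_rng(3).normal(size=(6, 2 * tiny_config.hidden))
    perm = np.random.default_rng(4).permutation(6)
    _, alpha = attention_pool(H, params["res_att_W"], params["res_att_b"],
                              params["res_att_u"])
    _, alpha_p = attention_pool(H[perm], params["res_att_W"], params["res_att_b"],
                                params["res_att_u"])
    np.testing.assert_allclose(alpha.data[perm], alpha_p.data, atol=1e-12)


# -- forward pass ------------------------------------------------------------


def test_forward_probabilities_and_trace_shapes(tiny_config):
    params = init_params(tiny_config, seed=1)
    frag = _fragment(tiny_config)
    p, trace = forward(frag, params, tiny_config)
    assert p.shape == (2,)
    assert (p >= 0).all()
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert len(trace.kmer_weights) == 3
    assert [len(w) for w in trace.residue_weights] == [3, 3, 1]
    assert trace.kmer_weights.sum() == pytest.approx(1.0, abs=1e-6)


def test_forward_padded_positions_zero_weight(tiny_config):
    params = init_params(tiny_config, seed=1)
    frag = _fragment(tiny_config, center=0, L=7)  # 3 leading pads
    _, trace = forward(frag, params, tiny_config)
    flat = np.concatenate(trace.residue_weights)
    assert (flat[:3] == 0).all()
    assert trace.kmer_weights[0] == 0.0  # first K-mer is fully padded


def test_forward_config_mismatch(tiny_config):
    params = init_params(tiny_config, seed=1)
    frag = _fragment(tiny_config)
    bad = dataclasses.replace(tiny_config, window=9)
    with pytest.raises(ValueError):
        forward_batch(frag.window_features[None], frag.pad_mask[None], params, bad)


# -- loss --------------------------------------------------------------------


def test_loss_perfect_prediction_near_zero():
    assert weighted_bce_loss([1], [1 - 1e-7], 7.0) == pytest.approx(0.0, abs=1e-6)


def test_loss_closed_forms():
    assert weighted_bce_loss([0, 1], [0.5, 0.5], 1.0) == pytest.approx(
        np.log(2), abs=1e-9
    )
    assert weighted_bce_loss([1], [0.5], 7.0) == pytest.approx(
        7 * np.log(2), abs=1e-9
    )


def test_loss_unit_weight_matches_plain_cross_entropy():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 64)
    p = rng.uniform(0.01, 0.99, 64)
    # independent plain implementation of the printed unweighted form
    expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert weighted_bce_loss(y, p, 1.0) == pytest.approx(expected, abs=1e-12)


def test_loss_length_mismatch():
    with pytest.raises(ValueError):
        weighted_bce_loss([1, 0], [0.5], 1.0)


# -- Adam --------------------------------------------------------------------


def test_adam_zero_gradient_no_update():
    params = {"w": np.array([1.0, -2.0])}
    new, _ = adam_step(params, {"w": np.zeros(2)}, {}, t=1)
    np.testing.assert_array_equal(new["w"], params["w"])


def test_adam_first_step_bias_correction():
    new, _ = adam_step({"w": np.array([1.0])}, {"w": np.array([1.0])}, {}, t=1,
                       alpha=0.1, eps=1e-8)
    assert new["w"][0] == pytest.approx(1.0 - 0.1, abs=1e-8)


def test_adam_matches_elementwise_reference_over_100_steps():
    """Oracle: an independent scalar-loop Adam, compared to 1e-10."""
    rng = np.random.default_rng(8)
    theta = rng.normal(size=7)
    ref_theta = theta.copy()
    m = np.zeros(7)
    v = np.zeros(7)
    state = {}
    a, b1, b2, eps = 0.01, 0.9, 0.999, 1e-8
    params = {"w": theta}
    for t in range(1, 101):
        g = rng.normal(size=7)
        params, state = adam_step(params, {"w": g}, state, t, a, b1, b2, eps)
        for i in range(7):  # naive per-element reference
            m[i] = b1 * m[i] + (1 - b1) * g[i]
            v[i] = b2 * v[i] + (1 - b2) * g[i] ** 2
            mh = m[i] / (1 - b1**t)
            vh = v[i] / (1 - b2**t)
            ref_theta[i] -= a * mh / (np.sqrt(vh) + eps)
    np.testing.assert_allclose(params["w"], ref_theta, atol=1e-10)


def test_adam_rejects_nonpositive_lr():
    with pytest.raises(ValueError):
        adam_step({"w": np.zeros(1)}, {"w": np.zeros(1)}, {}, 1, alpha=0.0)


# -- training ----------------------------------------------------------------


def test_train_deterministic(tiny_split):
    split, cfg = tiny_split
    p1, h1 = train(split, cfg)
    p2, h2 = train(split, cfg)
    for name in p1.tensors:
        np.testing.assert_array_equal(p1[name].data, p2[name].data)
    assert h1 == h2


def test_train_zero_epochs_returns_init(tiny_split):
    split, cfg = tiny_split
    cfg0 = dataclasses.replace(cfg, epochs=0)
    params, history = train(split, cfg0)
    assert history == []
    again, _ = train(split, cfg0)  # pure seeded initialisation
    for name in params.tensors:
        np.testing.assert_array_equal(params[name].data, again[name].data)
    # untrained: parameters differ from a 1-epoch run
    trained, _ = train(split, dataclasses.replace(cfg, epochs=1))
    assert any(
        not np.array_equal(params[n].data, trained[n].data) for n in params.tensors
    )


def test_train_empty_raises(tiny_config):
    with pytest.raises(ValueError):
        train(DatasetSplit([], [], 0), tiny_config)


def test_train_overfits_separable_fragments(tiny_corpus):
    """~100 separable fragments must be fittable to near-zero loss."""
    records, _, source = tiny_corpus
    cfg = TrainConfig(hidden=10, attention=8, projection=4, embed_dim=12,
                      epochs=30, seed=1, val_fraction=0.0, batch_size=8,
                      learning_rate=3e-3)
    from hanppis.fragmenter import fragment_protein

    frags = []
    for rec in records[:4]:
        frags.extend(fragment_protein(rec, source, cfg))
    split = DatasetSplit(frags[:100], [], 0)
    _, history = train(split, cfg)
    assert history[-1]["train_loss"] < 0.1


def test_predict_per_residue(tiny_corpus, tiny_config):
    records, _, source = tiny_corpus
    params = init_params(tiny_config, seed=0)
    rec = records[0]
    probs = predict(params, rec, source, tiny_config)
    assert probs.shape == (min(len(rec), tiny_config.max_len),)
    assert ((probs >= 0) & (probs <= 1)).all()
    np.testing.assert_array_equal(probs, predict(params, rec, source, tiny_config))


def test_predict_truncates_long_proteins(tiny_config):
    import dataclasses as dc

    from hanppis.io_features import ProteinRecord

    cfg = dc.replace(tiny_config, max_len=20)
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
    rec = ProteinRecord("long", seq)
    source = synth_feature_source([rec], sigma=0.0, seed=0, embed_dim=cfg.embed_dim)
    params = init_params(cfg, seed=0)
    assert predict(params, rec, source, cfg).shape == (20,)


# -- checkpointing -----------------------------------------------------------


def test_checkpoint_roundtrip(tmp_path, tiny_config):
    params = init_params(tiny_config, seed=4)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, tiny_config)
    loaded, cfg = load_checkpoint(path)
    assert cfg == tiny_config
    for name in params.tensors:
        np.testing.assert_array_equal(params[name].data, loaded[name].data)


# -- gradient oracle ---------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_gradients_match_central_differences(seed):
    """Analytic gradients of loss(forward) vs central finite differences."""
    cfg = TrainConfig(hidden=3, attention=3, projection=2, embed_dim=5, seed=0)
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(9, raw_width(cfg.embed_dim))).astype(np.float32)
    labels = np.zeros(9, dtype=np.int8)
    labels[4] = 1
    frag = extract_window(feats, "ACDEFGHIK", labels, 4, cfg.window, "p")
    params = init_params(cfg, seed=seed + 100)
    windows = frag.window_features[None].astype(np.float64)
    masks = frag.pad_mask[None].astype(np.float64)
    y = np.array([float(frag.label)])

    def loss_value():
        probs, _ = forward_batch(windows, masks, params, cfg)
        return weighted_bce_loss(y, probs[:, 1], 7.0)

    params.zero_grad()
    loss = loss_value()
    loss.backward()
    eps = 1e-5  # balances truncation (~eps^2) against round-off (~1e-11/eps)
    worst = 0.0
    for name, t in params.tensors.items():
        g = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        idx = np.random.default_rng(seed).choice(
            flat.size, size=min(10, flat.size), replace=False
        )
        for i in idx:
            old = flat[i]
            flat[i] = old + eps
            lp = loss_value().item()
            flat[i] = old - eps
            lm = loss_value().item()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = g.reshape(-1)[i]
            rel = abs(num - ana) / max(abs(num), abs(ana), 1e-8)
            worst = max(worst, rel)
    assert worst < 1e-4
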