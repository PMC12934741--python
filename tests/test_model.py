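"""C-GVAE model contracts: KL closed form, reparameterization, decoder
output structure, encoder invariances and checkpointing."""

import io

import numpy as np
import pytest

from cgvae import CGVAE, ModelConfig, kl_divergence, loss_total, reparameterize
from cgvae.graphs import BrainGraph, vector_to_symmetric
from cgvae.nn.model import collate
from cgvae.nn.tensor import Tensor

from oracle_utils import random_symmetric


def tiny_cfg(**kw):
    base = dict(encoder_type="gatv2", encoder_hidden=8, encoder_layers=2,
                heads=2, decoder_hidden=8, decoder_layers=2, latent_dim=4,
                dropout=0.0, max_nodes=6)
    base.update(kw)
    return ModelConfig(**base)


def make_graph(rng, n=6, condition=1.0):
    M = random_symmetric(rng, n, sparsity=0.3)
    src, dst = np.nonzero(M)
    g = BrainGraph(node_features=M, edge_index=np.stack([src, dst]),
                   condition=condition)
    iu = np.triu_indices(n, k=1)
    g.target = M[iu]
    return g


# -- KL divergence -----------------------------------------------------------

def test_kl_standard_normal_is_zero():
    assert kl_divergence(np.zeros(5), np.zeros(5)) == 0.0


def test_kl_unit_mean_case():
    # k=1, mu=1, sigma=1: 0.5 * (1 + 1 - 1 - 0) = 0.5
    assert kl_divergence(np.array([1.0]), np.array([0.0])) == 0.5


def test_kl_matches_closed_form_on_random_inputs(rng):
    for _ in range(100):
        shape = (int(rng.integers(1, 5)), int(rng.integers(1, 8)))
        mu = rng.normal(size=shape)
        logvar = rng.normal(scale=0.8, size=shape)
        want = 0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar)
        assert kl_divergence(mu, logvar) == pytest.approx(want, abs=1e-8)


def test_kl_is_nonnegative(rng):
    for _ in range(50):
        mu = rng.normal(size=10)
        logvar = rng.normal(size=10)
        assert kl_divergence(mu, logvar) >= 0.0


def test_kl_rejects_bad_inputs():
    with pytest.raises(ValueError, match="shape"):
        kl_divergence(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError, match="finite"):
        kl_divergence(np.array([np.nan]), np.zeros(1))


# -- reparameterization -------------------------------------------------------

def test_reparameterize_collapses_to_mean_at_tiny_variance(rng):
    mu = rng.normal(size=(4, 6))
    z = reparameterize(mu, np.full((4, 6), -60.0), rng)
    np.testing.assert_allclose(z, mu, atol=1e-10)


def test_reparameterize_moments(rng):
    mu = np.array([2.0, -1.0])
    logvar = np.array([np.log(4.0), np.log(0.25)])
    draws = np.stack([reparameterize(mu, logvar, rng) for _ in range(20000)])
    np.testing.assert_allclose(draws.mean(axis=0), mu, atol=0.1)
    np.testing.assert_allclose(draws.std(axis=0), [2.0, 0.5], atol=0.08)


def test_reparameterize_deterministic_given_seed():
    mu, lv = np.ones((2, 3)), np.zeros((2, 3))
    z1 = reparameterize(mu, lv, np.random.default_rng(9))
    z2 = reparameterize(mu, lv, np.random.default_rng(9))
    assert np.array_equal(z1, z2)


# -- loss --------------------------------------------------------------------

def test_loss_zero_for_perfect_reconstruction_at_prior(rng):
    x = rng.normal(size=15)
    rep = loss_total(x, x.copy(), np.zeros(4), np.zeros(4))
    assert rep.recon == 0.0 and rep.kl == 0.0 and rep.total == 0.0


def test_loss_hand_case_mean_reduction():
    # three edges off by 0.2 each: mean squared error = 0.04
    rec = np.array([0.2, 0.2, 0.2])
    tgt = np.zeros(3)
    rep = loss_total(rec, tgt, np.zeros(2), np.zeros(2))
    assert rep.recon == pytest.approx(0.04)
    rep = loss_total(rec, tgt, np.zeros(2), np.zeros(2), reduction="sum")
    assert rep.recon == pytest.approx(0.12)


def test_loss_accepts_matrices_and_uses_unique_edges(rng):
    A = random_symmetric(rng, 5)
    B = random_symmetric(rng, 5)
    iu = np.triu_indices(5, k=1)
    want = np.mean((A[iu] - B[iu]) ** 2)
    rep = loss_total(A, B, np.zeros(2), np.zeros(2))
    assert rep.recon == pytest.approx(want)


def test_loss_total_is_recon_plus_beta_kl(rng):
    x, y = rng.normal(size=10), rng.normal(size=10)
    mu, lv = rng.normal(size=3), rng.normal(size=3)
    for beta in (0.0, 0.5, 2.0):
        rep = loss_total(x, y, mu, lv, beta=beta)
        assert rep.total == pytest.approx(rep.recon + beta * rep.kl)
    rep0 = loss_total(x, y, mu, lv, beta=0.0)
    assert rep0.total == rep0.recon
    with pytest.raises(ValueError):
        loss_total(x, y, mu, lv, beta=-1.0)
    with pytest.raises(ValueError, match="shape"):
        loss_total(x, y[:5], mu, lv)


# -- model forward -----------------------------------------------------------

def test_decoder_output_is_symmetric_bounded_zero_diagonal(rng):
    model = CGVAE(tiny_cfg(), seed=3)
    model.eval()
    z = rng.normal(size=(2, 4))
    out = model.decode(Tensor(z), np.array([0.0, 1.0])).data
    assert out.shape == (2, 15)
    assert np.all(np.abs(out) < 1.0)  # tanh range
    M = vector_to_symmetric(out[0], 6)
    assert np.array_equal(M, M.T) and np.all(np.diag(M) == 0)


def test_decoder_depends_on_condition(rng):
    model = CGVAE(tiny_cfg(), seed=3)
    model.eval()
    z = rng.normal(size=(1, 4))
    d0 = model.decode(Tensor(z), np.array([0.0])).data
    d1 = model.decode(Tensor(z), np.array([1.0])).data
    assert not np.allclose(d0, d1)


def test_unconditional_model_ignores_conditions(rng):
    model = CGVAE(tiny_cfg(conditional=False), seed=3)
    model.eval()
    g1 = make_graph(np.random.default_rng(0), condition=0.0)
    g2 = make_graph(np.random.default_rng(0), condition=1.0)
    r1, *_ = model.forward(collate([g1]), sample=False)
    r2, *_ = model.forward(collate([g2]), sample=False)
    assert np.array_equal(r1.data, r2.data)


def test_posterior_heads_start_at_the_prior(rng):
    model = CGVAE(tiny_cfg(), seed=0)
    model.eval()
    g = make_graph(rng)
    mu, logvar = model.encode(collate([g]))
    assert np.all(mu.data == 0.0) and np.all(logvar.data == 0.0)


def test_eval_forward_is_deterministic(rng):
    model = CGVAE(tiny_cfg(dropout=0.2), seed=1)
    model.eval()
    g = make_graph(rng)
    batch = collate([g])
    r1, *_ = model.forward(batch, sample=False)
    r2, *_ = model.forward(batch, sample=False)
    assert np.array_equal(r1.data, r2.data)


def test_sampling_requires_rng(rng):
    model = CGVAE(tiny_cfg(), seed=1)
    with pytest.raises(ValueError, match="rng"):
        model.forward(collate([make_graph(rng)]), sample=True)


def test_node_relabeling_invariance(rng):
    """Permuting node order (rows of the feature matrix and edge labels)
    must not change the pooled graph embedding."""
    cfg = tiny_cfg()
    for enc in ("gatv2", "gat", "gcn", "gin"):
        model = CGVAE(tiny_cfg(encoder_type=enc), seed=2)
        model.eval()
        g = make_graph(np.random.default_rng(5))
        perm = np.random.default_rng(6).permutation(6)
        inv = np.argsort(perm)
        g2 = BrainGraph(
            node_features=g.node_features[perm],
            edge_index=inv[g.edge_index],
            condition=g.condition,
        )
        e1 = model.embed(collate([g])).data
        e2 = model.embed(collate([g2])).data
        np.testing.assert_allclose(e1, e2, atol=1e-8, err_msg=enc)


def test_mlp_baseline_ignores_edges(rng):
    model = CGVAE(tiny_cfg(encoder_type="mlp"), seed=2)
    model.eval()
    g = make_graph(rng)
    g_noedge = BrainGraph(node_features=g.node_features,
                          edge_index=np.zeros((2, 0), dtype=np.int64),
                          condition=g.condition)
    e1 = model.embed(collate([g])).data
    e2 = model.embed(collate([g_noedge])).data
    np.testing.assert_allclose(e1, e2)


def test_graph_encoders_use_edges(rng):
    g = make_graph(np.random.default_rng(7))
    g_noedge = BrainGraph(node_features=g.node_features,
                          edge_index=np.zeros((2, 0), dtype=np.int64),
                          condition=g.condition)
    for enc in ("gatv2", "gat", "gcn", "gin"):
        model = CGVAE(tiny_cfg(encoder_type=enc), seed=2)
        model.eval()
        e1 = model.embed(collate([g])).data
        e2 = model.embed(collate([g_noedge])).data
        assert not np.allclose(e1, e2), enc


def test_batch_independence(rng):
    """Graphs collated together give the same embeddings as alone."""
    model = CGVAE(tiny_cfg(), seed=4)
    model.eval()
    g1, g2 = make_graph(np.random.default_rng(1)), make_graph(np.random.default_rng(2))
    both = model.embed(collate([g1, g2])).data
    alone1 = model.embed(collate([g1])).data[0]
    alone2 = model.embed(collate([g2])).data[0]
    np.testing.assert_allclose(both[0], alone1, atol=1e-8)
    np.testing.assert_allclose(both[1], alone2, atol=1e-8)


def test_config_validation():
    with pytest.raises(ValueError, match="encoder_type"):
        ModelConfig(encoder_type="transformer")
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(encoder_hidden=10, heads=4)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.5)
    with pytest.raises(ValueError):
        ModelConfig(beta=-0.1)
    with pytest.raises(ValueError):
        ModelConfig(recon_reduction="median")
    assert ModelConfig(max_nodes=53).n_upper == 1378


def test_conditional_model_requires_conditions(rng):
    model = CGVAE(tiny_cfg(), seed=1)
    g = make_graph(rng, condition=None)
    with pytest.raises(ValueError, match="condition"):
        model.forward(collate([g]), sample=False)


def test_checkpoint_roundtrip(tmp_path, rng):
    model = CGVAE(tiny_cfg(), seed=8)
    # give the zero-initialized heads nonzero weights so the roundtrip
    # is informative
    model.mu_head.weight.data = rng.normal(size=model.mu_head.weight.data.shape)
    model.eval()
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = CGVAE.load(path)
    assert loaded.config == model.config
    g = make_graph(rng)
    batch = collate([g])
    r1, *_ = model.forward(batch, sample=False)
    r2, *_ = loaded.forward(batch, sample=False)
    assert np.array_equal(r1.data, r2.data)


def test_autodiff_loss_path_matches_public_contract(rng):
    """The Tensor-path loss equals loss_total computed per graph with
    sum reduction, averaged over the batch."""
    cfg = tiny_cfg()
    model = CGVAE(cfg, seed=9)
    model.eval()
    graphs = [make_graph(np.random.default_rng(i)) for i in range(3)]
    batch = collate(graphs)
    recon, mu, logvar, _ = model.forward(batch, sample=False)
    _, rep = model.loss(recon, batch.targets, mu, logvar)
    per_graph = [
        loss_total(recon.data[i], batch.targets[i], mu.data[i],
                   logvar.data[i], reduction="sum")
        for i in range(3)
    ]
    assert rep.recon == pytest.approx(np.mean([r.recon for r in per_graph]))
    assert rep.kl == pytest.approx(np.mean([r.kl for r in per_graph]))
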