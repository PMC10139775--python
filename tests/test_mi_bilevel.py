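"""The JS mutual-information bound and the pseudo bi-level optimiser:
closed forms, the theta-never-persisted contract, and the second-order
outer gradient against a finite-difference oracle."""
import numpy as np
import pytest

import structssl.autodiff as ad
from structssl.autodiff import Tensor
from structssl.encoders import seq_encode, seq_project
from structssl.mi import (
    BilevelConfig,
    derangement,
    discriminator_score,
    init_discriminator,
    inner_step,
    mi_estimate,
    outer_step,
    protein_level_reps,
)
from structssl.nn import tree_bytes, tree_from_arrays, tree_leaves, tree_tensors, tree_to_arrays
from structssl.objectives import sample_mask, ssl_loss
from structssl.pipeline import ModelConfig, init_model, prepare_proteins
from structssl.synth import make_toy_dataset


def _zero_discriminator(dim):
    beta = init_discriminator(np.random.default_rng(0), dim)
    for t in tree_tensors(beta):
        t.data = np.zeros_like(t.data)
    return beta


@pytest.fixture(scope="module")
def toy():
    """Three tiny proteins, parameters, embeddings and per-protein masks."""
    mc = ModelConfig(hidden_dim=3, emb_dim=2, rbf_centers=2, T=4, n_layers=1)
    prepared = prepare_proteins(make_toy_dataset(3, (4, 6), 3, seed=2).structures, mc)
    params = init_model(mc, 5)
    graphs = [p.graph for p in prepared]
    caches = [p.cache for p in prepared]
    rng = np.random.default_rng(9)
    masks = [sample_mask(g, 0.15, rng) for g in graphs]
    embs = [seq_encode(g.sequence, params["theta"]) for g in graphs]
    return mc, graphs, caches, params, masks, embs


def test_zero_discriminator_gives_minus_two_ln_two(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    beta = _zero_discriminator(mc.hidden_dim)
    neg = derangement(3, np.random.default_rng(0))
    I = mi_estimate(reps, beta, neg)
    assert I.item() == pytest.approx(-2 * np.log(2.0), abs=1e-9)


def test_mi_requires_at_least_two_proteins(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(graphs[:1], embs[:1], params["theta"], params["omega"], mc.rbf)
    with pytest.raises(ValueError):
        mi_estimate(reps, params["beta"], np.array([0]))
    with pytest.raises(ValueError):
        derangement(1, np.random.default_rng(0))


def test_derangement_has_no_fixed_points():
    rng = np.random.default_rng(1)
    for n in (2, 3, 8, 20):
        perm = derangement(n, rng)
        assert sorted(perm) == list(range(n))
        assert not np.any(perm == np.arange(n))


def test_identical_proteins_give_identical_reps(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(
        [graphs[0], graphs[0]], [embs[0], embs[0]], params["theta"], params["omega"], mc.rbf
    )
    assert np.array_equal(reps[0][0].data, reps[1][0].data)
    assert np.array_equal(reps[0][1].data, reps[1][1].data)


def test_sequence_rep_is_mean_of_projected_embeddings(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    expected = seq_project(params["theta"], embs[0]).data.mean(axis=0)
    assert np.allclose(reps[0][0].data[0], expected)


def test_inner_step_eta_zero_is_identity(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    I = mi_estimate(reps, params["beta"], derangement(3, np.random.default_rng(0)))
    theta_w = inner_step(params["theta"], I, 0.0)
    for (_, a), (_, b) in zip(tree_leaves(params["theta"]), tree_leaves(theta_w)):
        assert np.array_equal(a.data, b.data)


def test_inner_step_displacement_linear_in_eta(toy):
    mc, graphs, caches, params, _, embs = toy
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    I = mi_estimate(reps, params["beta"], derangement(3, np.random.default_rng(0)))
    t1 = inner_step(params["theta"], I, 1e-3)
    t2 = inner_step(params["theta"], I, 2e-3)
    for (_, base), (_, a), (_, b) in zip(
        tree_leaves(params["theta"]), tree_leaves(t1), tree_leaves(t2)
    ):
        assert np.allclose(b.data - base.data, 2 * (a.data - base.data), atol=1e-15)


def test_inner_step_is_an_ascent_direction(toy):
    mc, graphs, caches, params, _, embs = toy
    neg = derangement(3, np.random.default_rng(0))

    def mi_at(theta):
        reps = protein_level_reps(graphs, embs, theta, params["omega"], mc.rbf, caches)
        return mi_estimate(reps, params["beta"], neg)

    I0 = mi_at(params["theta"])
    theta_w = inner_step(params["theta"], I0, 1e-6, mode="first_order")
    assert mi_at(theta_w).item() >= I0.item() - 1e-12


def test_beta_gradient_ascent_monotonically_increases_mi(toy):
    mc, graphs, caches, params, _, embs = toy
    beta = init_discriminator(np.random.default_rng(7), mc.hidden_dim)
    neg = derangement(3, np.random.default_rng(0))
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    reps = [(Tensor(s.data), Tensor(g.data)) for s, g in reps]  # freeze inputs
    values = []
    for _ in range(50):
        I = mi_estimate(reps, beta, neg)
        values.append(I.item())
        grads = ad.grad(I, tree_tensors(beta))
        for t, g in zip(tree_tensors(beta), grads):
            t.data = t.data + 1e-3 * g.data
    assert np.min(np.diff(values)) > -1e-8


def test_trained_mi_separates_matched_from_shuffled_pairs():
    """When sequence identity determines structure class, the trained
    bound scores matched pairings above a shuffled pairing."""
    mc = ModelConfig(hidden_dim=6, emb_dim=4, rbf_centers=4, n_layers=1)
    from structssl.synth import make_ideal_helix, make_ideal_strand
    from structssl.structure import ProteinStructure

    helices = [make_ideal_helix(10, s) for s in (0, 1)]
    strands = [make_ideal_strand(10, s) for s in (2, 3)]
    structures = []
    for s, seq_char in zip(helices + strands, "AAVV"):
        structures.append(
            ProteinStructure(
                sequence=seq_char * 10,
                coords_N=s.coords_N,
                coords_CA=s.coords_CA,
                coords_C=s.coords_C,
            )
        )
    prepared = prepare_proteins(structures, mc)
    graphs = [p.graph for p in prepared]
    caches = [p.cache for p in prepared]
    params = init_model(mc, 3)
    embs = [seq_encode(g.sequence, params["theta"]) for g in graphs]
    reps = protein_level_reps(graphs, embs, params["theta"], params["omega"], mc.rbf, caches)
    reps = [(Tensor(s.data), Tensor(g.data)) for s, g in reps]
    matched_neg = np.array([2, 3, 0, 1])  # negatives cross the class boundary
    beta = init_discriminator(np.random.default_rng(11), mc.hidden_dim)
    for _ in range(200):
        I = mi_estimate(reps, beta, matched_neg)
        grads = ad.grad(I, tree_tensors(beta))
        for t, g in zip(tree_tensors(beta), grads):
            t.data = t.data + 1e-2 * g.data
    I_matched = mi_estimate(reps, beta, matched_neg).item()
    shuffled = [(reps[i][0], reps[j][1]) for i, j in enumerate([2, 3, 0, 1])]
    I_shuffled = mi_estimate(shuffled, beta, np.array([1, 0, 3, 2])).item()
    assert I_matched > I_shuffled


# ------------------------------------------------------------------ outer step
def test_outer_step_mode_off_equals_plain_gradients(toy):
    mc, graphs, caches, params, masks, embs = toy
    cfg = BilevelConfig(mode="off", mi_enabled=False)
    metrics = outer_step(
        params, graphs, masks, embs, cfg, np.random.default_rng(0),
        binning=mc.binning, rbf=mc.rbf, caches=caches,
    )
    _, _, total = ssl_loss(
        graphs, params["theta"], params["omega"], params["alpha"], masks, embs,
        mc.binning, mc.rbf, caches=caches,
    )
    plain = ad.grad(total, tree_tensors(params["omega"]) + tree_tensors(params["alpha"]))
    for g_step, g_plain in zip(metrics["grads"], plain):
        assert np.abs(g_step.data - g_plain.data).max() < 1e-12


def test_theta_bytes_unchanged_by_outer_steps(toy):
    mc, graphs, caches, params, masks, embs = toy
    from structssl.nn import Adam

    before = tree_bytes(params["theta"])
    opt = Adam(tree_tensors(params["omega"]) + tree_tensors(params["alpha"]), lr=1e-3)
    beta_opt = Adam(tree_tensors(params["beta"]), lr=1e-3, maximize=True)
    cfg = BilevelConfig(mode="second_order", inner_lr=5e-5)
    rng = np.random.default_rng(3)
    for _ in range(5):
        embs_now = [seq_encode(g.sequence, params["theta"]) for g in graphs]
        outer_step(
            params, graphs, masks, embs_now, cfg, rng,
            optimizer=opt, beta_optimizer=beta_opt,
            binning=mc.binning, rbf=mc.rbf, caches=caches,
        )
    assert tree_bytes(params["theta"]) == before


def test_second_order_outer_gradient_matches_finite_differences(toy):
    """Central differences of omega -> L(theta + eta dI/dtheta, omega, alpha)
    pin the full outer gradient, including the term through the inner step."""
    mc, graphs, caches, params, masks, embs = toy
    eta = 0.05
    neg = derangement(len(graphs), np.random.default_rng(42))

    def build(omega_arrays, mode):
        omega = tree_from_arrays(params["omega"], omega_arrays)
        embs_l = [seq_encode(g.sequence, params["theta"]) for g in graphs]
        reps = protein_level_reps(graphs, embs_l, params["theta"], omega, mc.rbf, caches)
        I = mi_estimate(reps, params["beta"], neg)
        theta_eff = inner_step(params["theta"], I, eta, mode)
        _, _, total = ssl_loss(
            graphs, theta_eff, omega, params["alpha"], masks, embs_l,
            mc.binning, mc.rbf, caches=caches,
        )
        return total, omega

    base = tree_to_arrays(params["omega"])
    total, omega_live = build(base, "second_order")
    analytic = ad.grad(total, tree_tensors(omega_live))
    total_fo, omega_fo = build(base, "first_order")
    first_order = ad.grad(total_fo, tree_tensors(omega_fo))

    def scalar_loss(omega_arrays):
        total, _ = build(omega_arrays, "first_order")
        return total.item()

    eps = 1e-5
    num = []
    for path in sorted(base):
        arr = base[path]
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            up = {p: a.copy() for p, a in base.items()}
            dn = {p: a.copy() for p, a in base.items()}
            up[path][idx] += eps
            dn[path][idx] -= eps
            num.append((scalar_loss(up) - scalar_loss(dn)) / (2 * eps))
    num = np.array(num)
    ana = np.concatenate([g.data.ravel() for g in analytic])
    fo = np.concatenate([g.data.ravel() for g in first_order])
    rel = np.linalg.norm(num - ana) / np.linalg.norm(num)
    assert rel < 1e-4
    # the second-order term is real: first-order mode deviates measurably more
    assert np.linalg.norm(num - fo) > 10 * np.linalg.norm(num - ana)
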