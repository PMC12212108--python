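"""Prototype layer, composite loss, projection, pruning, explanations."""

import numpy as np
import pytest

from protodbt.protopnet.model import (CLASS_NAMES, LossWeights, ProtoPNet,
                                      Prototype, TrainSchedule)


def tiny_model(**kw):
    kw.setdefault("in_size", 16)
    kw.setdefault("latent_dim", 4)
    kw.setdefault("channels", (4, 8))
    kw.setdefault("n_prototypes_per_class", 2)
    return ProtoPNet(**kw)


# -------------------------------------------------------- activation/scoring

def test_activation_map_closed_form_values():
    m = tiny_model(epsilon=1e-4)
    D = m.latent_dim
    p = Prototype(class_id=0, vector=np.zeros(D))
    latent = np.zeros((D, 2, 2))
    latent[0, 0, 1] = 1.0  # d2 = 1 at (0, 1), d2 = 0 elsewhere
    amap = m.compute_activation_map(latent, p)
    assert amap.shape == (2, 2)
    assert amap[0, 0] == pytest.approx(np.log(1.0 / 1e-4))  # ~9.2103
    assert amap[0, 0] == pytest.approx(9.2103, abs=1e-4)
    assert amap[0, 1] == pytest.approx(np.log(2.0 / 1.0001))  # ~0.6930
    assert amap[0, 1] == pytest.approx(0.6930, abs=1e-4)


def test_activation_strictly_decreasing_in_distance():
    m = tiny_model(epsilon=0.3)
    d2 = np.linspace(0, 50, 300)
    act = m.activation_from_distances(d2)
    assert np.all(np.diff(act) < 0)


def test_activation_dimension_mismatch_rejected():
    m = tiny_model()
    p = Prototype(class_id=0, vector=np.zeros(m.latent_dim + 1))
    with pytest.raises(ValueError):
        m.compute_activation_map(np.zeros((m.latent_dim, 2, 2)), p)


def test_similarity_scores_are_map_maxima_and_permutation_invariant(rng):
    m = tiny_model()
    latent = rng.uniform(0, 1, (m.latent_dim, 4, 4))
    scores = m.similarity_scores(latent)
    assert scores.shape == (m.n_prototypes,)
    for j, p in enumerate(m.prototypes):
        assert scores[j] == pytest.approx(m.compute_activation_map(latent, p).max())
    perm = rng.permutation(16)
    shuffled = latent.reshape(m.latent_dim, -1)[:, perm].reshape(latent.shape)
    assert m.similarity_scores(shuffled) == pytest.approx(scores)


def test_forward_probabilities_and_last_layer_sign_structure(rng):
    m = tiny_model()
    X = rng.integers(0, 256, (3, 16, 16), dtype=np.uint8)
    out = m.forward(X)
    assert out["probabilities"].shape == (3, 2)
    assert out["probabilities"].sum(axis=1) == pytest.approx(np.ones(3))
    # determinism
    assert np.array_equal(out["probabilities"], m.forward(X)["probabilities"])
    # +1 own-class / -0.5 cross-class: raising a cancer prototype's score
    # raises the cancer logit and lowers the benign logit
    cancer_idx = int(np.nonzero(m.prototype_classes == 1)[0][0])
    scores = out["scores"][0].copy()
    logits0 = m.W_last @ scores
    scores[cancer_idx] += 1.0
    logits1 = m.W_last @ scores
    assert logits1[1] > logits0[1] and logits1[0] < logits0[0]


# ---------------------------------------------------------------------- loss

def _brute_force_terms(model, z_batch, y):
    """Exhaustive enumeration of cluster/separation over patches (oracle)."""
    cluster, sep = [], []
    for zi, yi in zip(z_batch, y):
        d_same, d_other = [], []
        for p in model.prototypes:
            for h in range(zi.shape[1]):
                for w in range(zi.shape[2]):
                    d2 = float(((zi[:, h, w] - p.vector) ** 2).sum())
                    (d_same if p.class_id == yi else d_other).append(d2)
        cluster.append(min(d_same))
        sep.append(min(d_other))
    return float(np.mean(cluster)), float(-np.mean(sep))


def test_loss_reduces_to_cross_entropy_without_extra_terms(rng, small_crops):
    Xtr, ytr, _, _ = small_crops
    m = ProtoPNet(in_size=64, seed=1)
    terms = m.loss_terms(Xtr[:8], ytr[:8],
                         LossWeights(lambda_cluster=0.0, lambda_separation=0.0))
    assert terms["total"] == pytest.approx(terms["cross_entropy"])


def test_cluster_and_separation_match_bruteforce_enumeration(rng):
    m = tiny_model(seed=3)  # latent grid 4x4 but oracle iterates everything
    X = rng.integers(0, 256, (4, 16, 16), dtype=np.uint8)
    y = np.array([0, 1, 0, 1])
    out = m.forward(X)
    w = LossWeights(lambda_cluster=0.7, lambda_separation=0.3)
    terms = m._loss_from_forward(out, y, w)
    cluster, sep = _brute_force_terms(m, out["latent"], y)
    assert terms["cluster"] == pytest.approx(cluster, abs=1e-6)
    assert terms["separation"] == pytest.approx(sep, abs=1e-6)
    expected_total = (terms["cross_entropy"] + 0.7 * cluster + 0.3 * sep)
    assert terms["total"] == pytest.approx(expected_total, abs=1e-9)


def test_zero_distance_patch_gives_zero_cluster_contribution():
    m = tiny_model(seed=0)
    # craft a latent equal to a benign prototype everywhere
    z = np.tile(m.prototypes[0].vector[:, None, None], (1, 4, 4))[None]
    d2 = m._distances(z)
    same_min = d2[0, m.prototype_classes == 0].min()
    assert same_min == pytest.approx(0.0, abs=1e-12)


def test_loss_requires_prototypes_for_both_classes(rng, small_crops):
    Xtr, ytr, _, _ = small_crops
    m = ProtoPNet(in_size=64, seed=0)
    m.prototypes = [p for p in m.prototypes if p.class_id == 0]
    m.W_last = m.W_last[:, :len(m.prototypes)]
    with pytest.raises(ValueError, match="no prototype"):
        m.loss_terms(Xtr[:4], ytr[:4], LossWeights())


# ------------------------------------------------------------------ training

def test_history_bookkeeping_and_single_class_rejected(small_crops):
    Xtr, ytr, _, _ = small_crops
    m = ProtoPNet(in_size=64, latent_dim=8, channels=(4, 8), seed=0)
    sched = TrainSchedule(n_warmup_epochs=1, n_joint_epochs=1,
                          n_lastlayer_epochs=1, seed=0)
    m.fit(Xtr[:20], ytr[:20], sched)
    assert len(m.history) == 3
    assert [h["phase"] for h in m.history] == ["warmup", "joint", "last_layer"]
    assert all(p.provenance is not None for p in m.prototypes)
    with pytest.raises(ValueError, match="both classes"):
        ProtoPNet(in_size=64).fit(Xtr[:4], np.zeros(4, dtype=int), sched)


# ---------------------------------------------------------------- projection

def test_projection_idempotent_zero_distance_and_provenance(fitted_model,
                                                            small_crops):
    Xtr, ytr, _, _ = small_crops
    m = fitted_model
    P1 = m.prototype_matrix.copy()
    m.project_prototypes(Xtr, ytr)
    assert np.allclose(P1, m.prototype_matrix)
    patches, im_idx, pos = m._all_patches(Xtr)
    for p in m.prototypes:
        assert p.provenance is not None
        sel = (im_idx == p.provenance["image_index"]) & \
              (pos[:, 0] == p.provenance["grid_hw"][0]) & \
              (pos[:, 1] == p.provenance["grid_hw"][1])
        patch = patches[sel][0]
        assert np.allclose(patch, p.vector)  # post-projection distance 0
        # source image has the prototype's class
        assert ytr[p.provenance["image_index"]] == p.class_id


def test_projection_attains_map_maximum_on_source_image(fitted_model,
                                                        small_crops):
    Xtr, _, _, _ = small_crops
    m = fitted_model
    for p in m.prototypes[:4]:
        z = m._latent(m._prepare(Xtr[p.provenance["image_index"]]))[0]
        amap = m.compute_activation_map(z, p)
        h, w = np.unravel_index(amap.argmax(), amap.shape)
        assert (int(h), int(w)) == tuple(p.provenance["grid_hw"])


def test_projection_single_image_per_class(small_crops):
    Xtr, ytr, _, _ = small_crops
    i0 = int(np.nonzero(ytr == 0)[0][0])
    i1 = int(np.nonzero(ytr == 1)[0][0])
    m = ProtoPNet(in_size=64, latent_dim=4, channels=(4, 8), seed=2)
    m.project_prototypes(Xtr[[i0, i1]], ytr[[i0, i1]])
    for p in m.prototypes:
        expect = 0 if p.class_id == 0 else 1
        assert p.provenance["image_index"] == expect


# ------------------------------------------------------------------- pruning

def test_pruning_monotone_with_per_class_floor(fitted_model, small_crops):
    import copy

    Xtr, ytr, _, _ = small_crops
    m = copy.deepcopy(fitted_model)
    n0 = m.n_prototypes
    m.prune_prototypes(Xtr, ytr, k_nearest=6, purity_threshold=0.5)
    assert m.n_prototypes <= n0
    for c in (0, 1):
        assert any(p.class_id == c for p in m.prototypes)
    assert m.W_last.shape[1] == m.n_prototypes
    # a lenient threshold removes nothing
    m2 = copy.deepcopy(fitted_model)
    m2.prune_prototypes(Xtr, ytr, k_nearest=6, purity_threshold=0.0)
    assert m2.n_prototypes == fitted_model.n_prototypes
    # an impossible threshold keeps exactly one (highest-purity) per class
    m3 = copy.deepcopy(fitted_model)
    m3.prune_prototypes(Xtr, ytr, k_nearest=6, purity_threshold=1.1)
    assert m3.n_prototypes == 2
    assert sorted(p.class_id for p in m3.prototypes) == [0, 1]


# -------------------------------------------------------------- explanations

def test_explanation_ranking_and_source_classes(fitted_model, small_crops):
    _, _, Xte, _ = small_crops
    m = fitted_model
    e = m.explain(Xte[0], k=5)
    sims = [it["similarity"] for it in e.items]
    assert sims == sorted(sims, reverse=True)
    assert len(e.items) == 5
    for it in e.items:
        # default scope: evidence comes from the predicted class's prototypes
        assert it["prototype_class"] == e.predicted_class
        src = it["source"]
        assert src is not None and "pixel_rect" in src
    top1 = m.explain(Xte[0], k=1)
    assert top1.items[0]["prototype_index"] == e.items[0]["prototype_index"]
    # scope="all" ranks across both classes and clips k to the prototype count
    with pytest.warns(UserWarning, match="clipping"):
        big = m.explain(Xte[0], k=m.n_prototypes + 3, scope="all")
    assert len(big.items) == m.n_prototypes
    all_sims = [it["similarity"] for it in big.items]
    assert all_sims == sorted(all_sims, reverse=True)
    assert set(it["prototype_class"] for it in big.items) <= set(CLASS_NAMES)


def test_checkpoint_round_trip(tmp_path, fitted_model, small_crops):
    _, _, Xte, _ = small_crops
    m = fitted_model
    path = m.save(tmp_path / "ckpt.npz")
    m2 = ProtoPNet.load(path)
    assert np.allclose(m.predict_proba(Xte), m2.predict_proba(Xte))
    assert m2.n_prototypes == m.n_prototypes
    assert m2.prototypes[0].provenance == m.prototypes[0].provenance
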