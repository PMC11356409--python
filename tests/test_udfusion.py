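"""Fusion-weight math, entropy closed forms, and autoencoder contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sats.synthetic import DomainDataset, make_domain_style, render_polyp_image
from sats.udfusion import (AETrainConfig, FusionMode, distribution_weights,
                           fuse_pseudo_label, pixel_uncertainty,
                           reconstruction_distance, train_autoencoder,
                           udfusion, uncertainty_weights)


# -- distribution weights (softmax over negated distances) --------------------

def test_distribution_weights_symmetry_and_limits():
    np.testing.assert_allclose(distribution_weights([0.4, 0.4, 0.4]),
                               1.0 / 3, atol=1e-12)
    u = distribution_weights([0.0, 50.0, 50.0])
    np.testing.assert_allclose(u, [1.0, 0.0, 0.0], atol=1e-9)
    # high-precision scalar evaluation of softmax(-D)
    u = distribution_weights([0.1, 0.2, 0.3])
    np.testing.assert_allclose(u, [0.36716541, 0.33222499, 0.30060961],
                               atol=1e-7)
    assert u.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        distribution_weights([0.1, np.nan])


def test_distribution_weight_monotone_in_distance():
    """Decreasing one teacher's distance never decreases its weight."""
    base = np.array([0.5, 0.8, 1.1])
    prev = distribution_weights(base)[0]
    for d0 in (0.4, 0.3, 0.1, 0.0):
        cur = distribution_weights([d0, 0.8, 1.1])[0]
        assert cur >= prev
        prev = cur


# -- entropy ------------------------------------------------------------------

def test_pixel_uncertainty_closed_forms():
    assert pixel_uncertainty(np.array(1.0)) == pytest.approx(0.0, abs=1e-7)
    assert pixel_uncertainty(np.array(0.0)) == pytest.approx(0.0, abs=1e-7)
    assert pixel_uncertainty(np.array(0.5)) == pytest.approx(
        0.5 * np.log(2.0), abs=1e-7)
    grid = np.linspace(0.0, 1.0, 100001)
    u = pixel_uncertainty(grid)
    assert grid[np.argmax(u)] == pytest.approx(np.exp(-1.0), abs=1e-3)
    assert u.max() == pytest.approx(np.exp(-1.0), abs=1e-5)
    assert (u >= 0).all()
    with pytest.raises(ValueError):
        pixel_uncertainty(np.array(1.5))


def test_binary_entropy_variant_peaks_at_half():
    grid = np.linspace(0.0, 1.0, 10001)
    u = pixel_uncertainty(grid, binary=True)
    assert grid[np.argmax(u)] == pytest.approx(0.5, abs=1e-3)
    assert u.max() == pytest.approx(np.log(2.0), abs=1e-4)


def test_uncertainty_weights_contracts():
    same = np.full((3, 4, 4), 0.2)
    np.testing.assert_allclose(uncertainty_weights(same), 1.0 / 3,
                               atol=1e-12)
    u_maps = np.zeros((2, 1, 1))
    u_maps[1] = 10.0
    v = uncertainty_weights(u_maps)
    np.testing.assert_allclose(v[0], 1.0, atol=1e-4)
    # scalar evaluation at one pixel, k=2, U = (0.1, 0.4)
    v = uncertainty_weights(np.array([0.1, 0.4]).reshape(2, 1, 1))
    np.testing.assert_allclose(v[:, 0, 0], [0.57444252, 0.42555748],
                               atol=1e-7)
    with pytest.raises(ValueError):
        uncertainty_weights(np.zeros((2, 4)))


# -- fusion -------------------------------------------------------------------

def test_fusion_hand_example():
    """k=2 single pixel: yhat=(0.8,0.2), u=(0.7,0.3), v=(0.6,0.4)
    -> w=(0.65,0.35), fused 0.59."""
    preds = np.array([0.8, 0.2]).reshape(2, 1, 1)
    u = np.array([0.7, 0.3])
    v = np.array([0.6, 0.4]).reshape(2, 1, 1)
    fused, weights = fuse_pseudo_label(preds, u, v, FusionMode.UDFUSION)
    np.testing.assert_allclose(weights.w_maps[:, 0, 0], [0.65, 0.35],
                               atol=1e-12)
    assert fused[0, 0] == pytest.approx(0.59, abs=1e-12)


def test_fusion_k1_and_one_hot_endpoints(rng):
    pred = rng.uniform(size=(1, 4, 4))
    for mode in FusionMode:
        fused, _ = fuse_pseudo_label(pred, np.array([1.0]),
                                     np.ones((1, 4, 4)), mode)
        np.testing.assert_allclose(fused, pred[0], atol=1e-12)
    preds = rng.uniform(size=(3, 4, 4))
    u = np.array([0.0, 1.0, 0.0])
    v = np.zeros((3, 4, 4))
    v[1] = 1.0
    fused, _ = fuse_pseudo_label(preds, u, v, FusionMode.UDFUSION)
    np.testing.assert_allclose(fused, preds[1], atol=1e-12)


@given(st.integers(0, 2 ** 32 - 1), st.integers(2, 5))
@settings(max_examples=25, deadline=None)
def test_fusion_simplex_and_convexity_invariants(seed, k):
    rng = np.random.default_rng(seed)
    preds = rng.uniform(size=(k, 3, 3))
    distances = rng.uniform(0.0, 2.0, size=k)
    for mode in FusionMode:
        fused, w = udfusion(preds, distances, mode)
        np.testing.assert_allclose(w.u.sum(), 1.0, atol=1e-9)
        assert (w.u >= 0).all()
        np.testing.assert_allclose(w.v_maps.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(w.w_maps.sum(axis=0), 1.0, atol=1e-9)
        assert (fused >= preds.min(axis=0) - 1e-12).all()
        assert (fused <= preds.max(axis=0) + 1e-12).all()


def test_udfusion_weights_average_distance_and_uncertainty_modes(rng):
    preds = rng.uniform(size=(3, 4, 4))
    distances = rng.uniform(0.0, 1.0, size=3)
    _, w_ud = udfusion(preds, distances, FusionMode.UDFUSION)
    _, w_d = udfusion(preds, distances, FusionMode.DISTANCE_ONLY)
    _, w_u = udfusion(preds, distances, FusionMode.UNCERTAINTY_ONLY)
    np.testing.assert_allclose(w_ud.w_maps,
                               (w_d.w_maps + w_u.w_maps) / 2.0, atol=1e-12)
    # identical teachers: all modes agree
    same = np.tile(preds[:1], (3, 1, 1))
    fused_ud, _ = udfusion(same, distances, FusionMode.UDFUSION)
    fused_mean, _ = udfusion(same, distances, FusionMode.MEAN)
    np.testing.assert_allclose(fused_ud, fused_mean, atol=1e-12)


def test_fusion_beats_mean_when_nearest_teacher_is_right(rng):
    """Teacher 1 predicts the truth confidently, the others are confidently
    wrong but farther by reconstruction distance: UDFusion's label overlaps
    the truth at least as well as plain averaging."""
    truth = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
    good = np.clip(truth, 0.02, 0.98)
    bad = np.clip(1.0 - truth, 0.02, 0.98)
    preds = np.stack([good, bad, bad])
    distances = np.array([0.05, 1.0, 1.0])
    fused_ud, _ = udfusion(preds, distances, FusionMode.UDFUSION)
    fused_mean, _ = udfusion(preds, distances, FusionMode.MEAN)

    def dice(p):
        b = p > 0.5
        t = truth > 0.5
        return 2 * np.count_nonzero(b & t) / (b.sum() + t.sum())

    assert dice(fused_ud) >= dice(fused_mean)


def test_fusion_shape_errors(rng):
    preds = rng.uniform(size=(2, 4, 4))
    with pytest.raises(ValueError):
        fuse_pseudo_label(preds, np.array([1.0]), np.ones((2, 4, 4)),
                          FusionMode.MEAN)


# -- autoencoder --------------------------------------------------------------

def _constant_dataset(value, n=8, size=32):
    images = np.full((n, size, size, 3), value, dtype=np.float32)
    style = make_domain_style(1, 0)
    return DomainDataset(domain_id=1, name="const", style=style,
                         images=images, masks=None, labeled=False,
                         sample_seeds=list(range(n)))


def test_autoencoder_objective_decreases_and_is_deterministic():
    ds = _constant_dataset(0.6)
    cfg = AETrainConfig(epochs=3, seed=1)
    model, curve = train_autoencoder(ds, cfg)
    assert curve[-1] < curve[0]
    _, curve2 = train_autoencoder(ds, cfg)
    assert curve == curve2
    with pytest.raises(ValueError):
        train_autoencoder(_constant_dataset(0.5, n=0), cfg)


def test_reconstruction_distance_properties():
    ds = _constant_dataset(0.6)
    model, _ = train_autoencoder(ds, AETrainConfig(epochs=3, seed=1))
    d = reconstruction_distance(model, ds.images[0])
    assert d >= 0
    # pure function of pixel values: a copy gives the identical distance
    assert reconstruction_distance(
        model, ds.images[0].copy()) == pytest.approx(d, abs=0)


def test_hand_mse_distance():
    """Distance is the plain mean of squared residuals (hand arithmetic)."""

    class IdentityAE:
        def reconstruct(self, images):
            return images + 0.5   # known residual

    img = np.zeros((2, 2, 3), dtype=np.float32)
    assert reconstruction_distance(IdentityAE(), img) == pytest.approx(0.25)

    class PerfectAE:
        def reconstruct(self, images):
            return images.copy()

    assert reconstruction_distance(PerfectAE(), img) == pytest.approx(0.0)


def test_autoencoder_prefers_its_own_domain():
    """Small-scale version of the domain-separation property: an AE trained
    on one style reconstructs that style better than a >=45-degree-shifted
    style."""
    s1 = make_domain_style(1, 0)
    s2 = make_domain_style(2, 0)
    n = 16
    imgs1 = np.stack([render_polyp_image(s1, 32, 32, i).image
                      for i in range(n)])
    imgs2 = np.stack([render_polyp_image(s2, 32, 32, i).image
                      for i in range(n)])
    ds = DomainDataset(domain_id=1, name="d1", style=s1, images=imgs1,
                       masks=None, labeled=False, sample_seeds=list(range(n)))
    model, _ = train_autoencoder(ds, AETrainConfig(epochs=25, seed=3))
    own = np.mean((model.reconstruct(imgs1) - imgs1) ** 2)
    cross = np.mean((model.reconstruct(imgs2) - imgs2) ** 2)
    assert own < cross
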