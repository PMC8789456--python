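"""Capsule/bottleneck encoders, routing, fusion, entropy selection."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hemofuse.features import (
    BottleneckEncoderConfig,
    CapsEncoderConfig,
    bottleneck_encode,
    capsnet_encode,
    capsnet_shape_trace,
    column_entropy,
    dynamic_routing,
    entropy_select,
    fuse_features,
    init_block_weights,
    inverted_bottleneck_block,
    squash,
)


# -------------------------------------------------------------- squash

def test_squash_zero_fixed_point():
    assert np.array_equal(squash(np.zeros(4)), np.zeros(4))


def test_squash_unit_norm_halves():
    v = np.array([1.0, 0.0, 0.0])
    assert np.linalg.norm(squash(v)) == pytest.approx(0.5, abs=1e-12)


def test_squash_asymptote():
    assert np.linalg.norm(squash(1e6 * np.array([1.0, 0.0]))) > 0.999999


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.01, 50.0), st.floats(1.01, 3.0))
def test_squash_norm_monotone_and_direction_preserving(norm, factor):
    v = np.array([norm, 0.0])
    a, b = squash(v), squash(factor * v)
    assert np.linalg.norm(b) > np.linalg.norm(a)
    assert np.linalg.norm(a) < 1.0
    assert a[0] > 0 and a[1] == 0  # direction preserved


# -------------------------------------------------------------- routing

def test_routing_singleton_coupling_is_one():
    rng = np.random.default_rng(0)
    pred = rng.normal(size=(1, 1, 5))
    v, cs = dynamic_routing(pred, 3, return_couplings=True)
    assert all(np.allclose(c, 1.0) for c in cs)
    assert np.allclose(v[0], squash(pred[0, 0]))


def test_routing_symmetric_predictions_uniform_couplings():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(3, 1, 4))
    pred = np.repeat(base, 4, axis=1)  # identical across 4 output capsules
    _, cs = dynamic_routing(pred, 1, return_couplings=True)
    assert np.allclose(cs[0], 0.25)


def test_routing_matches_manual_unrolled_oracle():
    """2 inputs x 2 outputs, 3 iterations, recomputed step by step with
    explicit scalar arithmetic."""
    rng = np.random.default_rng(2)
    pred = rng.normal(size=(2, 2, 3))

    def sq(v):
        n2 = sum(x * x for x in v)
        return [(n2 / (1 + n2)) * x / (n2**0.5 + 1e-300) for x in v]

    logits = [[0.0, 0.0], [0.0, 0.0]]
    for _ in range(3):
        coup = []
        for i in range(2):
            mx = max(logits[i])
            e = [np.exp(l - mx) for l in logits[i]]
            z = sum(e)
            coup.append([x / z for x in e])
        outs = []
        for j in range(2):
            s = [sum(coup[i][j] * pred[i, j, d] for i in range(2)) for d in range(3)]
            outs.append(sq(s))
        for i in range(2):
            for j in range(2):
                logits[i][j] += sum(pred[i, j, d] * outs[j][d] for d in range(3))

    v = dynamic_routing(pred, 3)
    assert np.allclose(v, np.array(outs), atol=1e-12)


def test_routing_couplings_sum_to_one_every_iteration():
    rng = np.random.default_rng(3)
    pred = rng.normal(size=(7, 4, 6))
    _, cs = dynamic_routing(pred, 4, return_couplings=True)
    for c in cs:
        assert np.allclose(c.sum(axis=1), 1.0, atol=1e-9)


def test_routing_requires_iterations():
    with pytest.raises(ValueError):
        dynamic_routing(np.zeros((2, 2, 2)), 0)


# -------------------------------------------------------------- encoders

def test_capsnet_default_length_and_determinism(rng):
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    a = capsnet_encode(img)
    assert a.shape == (186,)
    assert np.array_equal(a, capsnet_encode(img))


def test_capsnet_entity_norms_below_one(rng):
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    cfg = CapsEncoderConfig()
    v = capsnet_encode(img, cfg).reshape(cfg.entity_caps, cfg.entity_dim)
    norms = np.linalg.norm(v, axis=1)
    assert np.all(norms >= 0) and np.all(norms < 1.0)


def test_capsnet_nine_capsule_config(rng):
    # a 9-entity-capsule configuration remains supported
    cfg = CapsEncoderConfig(entity_caps=9, entity_dim=8)
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    assert capsnet_encode(img, cfg).shape == (72,)


def test_capsnet_shape_trace_both_resolutions():
    cfg = CapsEncoderConfig()
    for size in (64, 512):
        trace = capsnet_shape_trace(cfg, size, size)
        assert trace["output_dim"] == 186
    with pytest.raises(ValueError):
        capsnet_shape_trace(cfg, 6, 6)


def test_bottleneck_default_length_and_determinism(rng):
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    b = bottleneck_encode(img)
    assert b.shape == (1000,)
    assert np.array_equal(b, bottleneck_encode(img))


def test_bottleneck_zero_input_finite():
    z = bottleneck_encode(np.zeros((64, 64), dtype=np.uint8))
    assert np.all(np.isfinite(z))


def test_residual_block_identity_with_zero_compress(rng):
    x = rng.normal(size=(8, 12, 12))
    w = init_block_weights(rng, 8, 8, 4)
    w["compress"] = np.zeros_like(w["compress"])
    assert np.allclose(inverted_bottleneck_block(x, w, stride=1), x)


def test_bottleneck_config_validation():
    with pytest.raises(ValueError):
        BottleneckEncoderConfig(expansion=0).validate()
    with pytest.raises(ValueError):
        BottleneckEncoderConfig(output_dim=0).validate()


# -------------------------------------------------------------- fusion

def test_fuse_lengths_and_split(rng):
    a, b = rng.normal(size=186), rng.normal(size=1000)
    f = fuse_features(a, b)
    assert len(f) == 1186 and (f.n, f.m) == (186, 1000)
    ra, rb = f.split()
    assert np.array_equal(ra, a) and np.array_equal(rb, b)


def test_fuse_empty_identity(rng):
    b = rng.normal(size=5)
    f = fuse_features(np.array([]), b)
    assert np.array_equal(f.values, b)


def test_fuse_rejects_nonfinite():
    with pytest.raises(ValueError):
        fuse_features(np.array([np.nan]), np.array([1.0]))


# -------------------------------------------------------------- entropy

def test_constant_column_zero_entropy_ranked_last(rng):
    X = rng.normal(size=(40, 4))
    X[:, 2] = 3.14
    ent = column_entropy(X)
    assert ent[2] == 0.0
    assert 2 not in entropy_select(X, keep=3)


def test_uniform_sixteen_centers_four_bits():
    col = np.tile(np.arange(16.0), 4)
    X = col[:, None]
    assert column_entropy(X, bins=16)[0] == pytest.approx(4.0, abs=1e-12)


def test_entropy_select_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 10)) * rng.uniform(0.1, 3.0, size=10)
    X[:, 7] = 0.0

    def oracle_entropy(col, bins=16):
        lo, hi = min(col), max(col)
        if hi <= lo:
            return 0.0
        counts = [0] * bins
        for v in col:
            b = min(int((v - lo) / (hi - lo) * bins), bins - 1)
            counts[b] += 1
        return -sum(
            (c / len(col)) * np.log2(c / len(col)) for c in counts if c > 0
        )

    ent = [oracle_entropy(X[:, j].tolist()) for j in range(10)]
    expected = sorted(sorted(range(10), key=lambda j: (-ent[j], j))[:6])
    assert np.array_equal(entropy_select(X, keep=6), expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_entropy_select_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(30, 8)) * rng.uniform(0.01, 5.0, size=8)
    ent = column_entropy(X)
    assume(len(set(ent.tolist())) == 8)  # ties break by index, not equivariant
    perm = rng.permutation(8)
    sel = set(entropy_select(X, keep=4).tolist())
    sel_p = set(entropy_select(X[:, perm], keep=4).tolist())
    assert {int(perm[j]) for j in sel_p} == sel


def test_entropy_select_keep_too_large():
    with pytest.raises(ValueError):
        entropy_select(np.zeros((5, 3)), keep=4)
    with pytest.raises(ValueError):
        column_entropy(np.zeros((5, 3)), bins=1)
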