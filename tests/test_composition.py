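"""Aitchison-geometry primitives: closure, ilr, means, variation matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from codasub.composition import (
    Composition,
    CompositionError,
    IlrTransformer,
    SequentialBinaryPartition,
    close,
    compositional_mean,
    ilr,
    ilr_inverse,
    lr_covariance_to_variation,
    replace_zeros,
    variation_matrix,
    variation_to_lr_covariance,
)
from codasub.simulate import TARGET_VARIATION

PARTS = ("sleep", "st", "lpa", "mvpa")
MEAN_DAY = (548.6, 510.3, 354.8, 26.4)

positive_comps = arrays(
    float, 4, elements=st.floats(0.5, 1400.0, allow_nan=False))


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values, kappa, expected", [
    ((360, 360, 360, 360), 1440, (360, 360, 360, 360)),
    ((2, 1, 1), 4, (2, 1, 1)),
])
def test_close_already_closed(values, kappa, expected):
    parts = PARTS[: len(values)]
    c = close(values, kappa, parts)
    np.testing.assert_allclose(c.values, expected, rtol=1e-12)
    assert c.is_closed


def test_close_preserves_ratios():
    c = close(MEAN_DAY, 1440, PARTS)
    assert c.values.sum() == pytest.approx(1440, rel=1e-12)
    ratios = np.asarray(MEAN_DAY) / MEAN_DAY[0]
    np.testing.assert_allclose(c.values / c.values[0], ratios, rtol=1e-12)


def test_close_idempotent():
    c = close((100.0, 3.0, 77.0, 900.0))
    np.testing.assert_array_equal(c.close().values, c.values)


def test_close_rejects_nonpositive_naming_part():
    with pytest.raises(CompositionError, match="lpa"):
        close((10, 10, 0, 10), 1440, PARTS)
    with pytest.raises(CompositionError, match="mvpa"):
        close((10, 10, 10, -1), 1440, PARTS)


def test_composition_label_validation():
    with pytest.raises(CompositionError, match="unique"):
        Composition(np.ones(4), ("a", "a", "b", "c"))
    with pytest.raises(CompositionError):
        Composition(np.ones(3), PARTS)


# ---------------------------------------------------------------------------
# sequential binary partitions
# ---------------------------------------------------------------------------

def test_contrast_columns_orthonormal_and_zero_sum(bases):
    for sbp in bases:
        psi = sbp.contrast_matrix
        np.testing.assert_allclose(psi.T @ psi, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(psi.sum(axis=0), 0.0, atol=1e-12)


def test_sbp_rejects_invalid_sign_matrices():
    with pytest.raises(CompositionError):  # bad entries
        SequentialBinaryPartition([[2, 0, 0], [1, 1, 0], [-1, -1, 1], [-1, 0, -1]])
    with pytest.raises(CompositionError, match="at least one"):
        SequentialBinaryPartition(
            np.array([[1, 1, 0], [1, 1, 0], [-1, 0, 0], [-1, 0, 0]]))
    # non-nested: second balance straddles both groups of the first split
    with pytest.raises(CompositionError, match="single group"):
        SequentialBinaryPartition(
            np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 1], [-1, -1, -1]]))


# ---------------------------------------------------------------------------
# ilr and its inverse
# ---------------------------------------------------------------------------

def test_ilr_of_uniform_is_zero():
    z = ilr(close((360, 360, 360, 360), 1440, PARTS))
    np.testing.assert_allclose(z.values, 0.0, atol=1e-12)


def test_ilr_scale_invariance():
    x = np.array(MEAN_DAY)
    sbp = SequentialBinaryPartition.pivot(PARTS)
    z1 = ilr(x, sbp).values
    z2 = ilr(2.0 * x, sbp).values
    np.testing.assert_allclose(z1, z2, rtol=1e-12)


def test_ilr_matches_clr_projection_oracle():
    """Independent route: centred log-ratio then projection on the contrasts."""
    sbp = SequentialBinaryPartition.pivot(PARTS)
    x = np.array(MEAN_DAY)
    clr = np.log(x) - np.log(x).mean()
    np.testing.assert_allclose(ilr(x, sbp).values, clr @ sbp.contrast_matrix,
                               rtol=1e-12)
    # explicit pivot-balance formula, written out independently
    expected = [np.sqrt((4 - k - 1) / (4 - k))
                * np.log(x[k] / np.exp(np.mean(np.log(x[k + 1:]))))
                for k in range(3)]
    np.testing.assert_allclose(ilr(x, sbp).values, expected, rtol=1e-10)


def test_ilr_matches_skbio():
    """Cross-check against scikit-bio with the identical partition."""
    from skbio.stats.composition import ilr as skbio_ilr, sbp_basis

    sbp = SequentialBinaryPartition.pivot(PARTS)
    basis = sbp_basis(sbp.sign_matrix.T)
    x = np.array(MEAN_DAY) / np.sum(MEAN_DAY)
    np.testing.assert_allclose(ilr(np.array(MEAN_DAY), sbp).values,
                               skbio_ilr(x, basis=basis), rtol=1e-10)


def test_ilr_dimension_and_label_mismatch():
    sbp = SequentialBinaryPartition.pivot(("a", "b", "c"))
    with pytest.raises(CompositionError):
        ilr(np.ones(4), sbp)
    with pytest.raises(CompositionError, match="labels"):
        ilr(close((1, 1, 1), 3, ("x", "y", "z")), sbp)


def test_ilr_inverse_zero_vector_is_uniform():
    sbp = SequentialBinaryPartition.pivot(PARTS)
    c = ilr_inverse(np.zeros(3), 1440, sbp)
    np.testing.assert_allclose(c.values, 360.0, rtol=1e-12)


def test_ilr_inverse_requires_basis():
    with pytest.raises(CompositionError, match="basis"):
        ilr_inverse(np.zeros(3))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(positive_comps)
def test_ilr_round_trip_identity(values):
    c = close(values, 1440, PARTS)
    back = ilr_inverse(ilr(c))
    np.testing.assert_allclose(back.values, c.values, rtol=1e-9)


def test_inverse_is_basis_invariant(bases):
    c = close(MEAN_DAY, 1440, PARTS)
    recovered = [ilr_inverse(ilr(c, sbp)).values for sbp in bases]
    for r in recovered[1:]:
        np.testing.assert_allclose(r, recovered[0], rtol=1e-10)


# ---------------------------------------------------------------------------
# compositional mean
# ---------------------------------------------------------------------------

def test_mean_of_identical_samples(rng):
    c = close(MEAN_DAY, 1440, PARTS)
    m = compositional_mean([c] * 5)
    np.testing.assert_allclose(m.values, c.values, rtol=1e-10)


def test_mean_matches_hand_computed_geometric_means():
    # geometric means of (1,2,4,8) and (4,2,1,8) are (2,2,2,8); they sum
    # to 14, so closure to kappa=15 scales every part by 15/14
    a = Composition(np.array([1.0, 2.0, 4.0, 8.0]), PARTS, 15)
    b = Composition(np.array([4.0, 2.0, 1.0, 8.0]), PARTS, 15)
    m = compositional_mean([a, b], kappa=15)
    np.testing.assert_allclose(m.values, np.array([2, 2, 2, 8]) * 15 / 14,
                               rtol=1e-12)
    assert m.values.sum() == pytest.approx(15.0, rel=1e-12)


def test_ilr_mean_equals_closed_geometric_means(rng):
    X = rng.lognormal(size=(50, 4), sigma=0.4) * [500, 480, 300, 30]
    m = compositional_mean(X, 1440, PARTS)
    g = np.exp(np.log(X).mean(axis=0))
    np.testing.assert_allclose(m.values, g * 1440 / g.sum(), rtol=1e-9)


def test_mean_is_basis_invariant(rng, bases):
    X = rng.lognormal(size=(30, 4), sigma=0.3) * [500, 480, 300, 30]
    means = [compositional_mean(X, 1440, PARTS, sbp).values for sbp in bases]
    for m in means[1:]:
        np.testing.assert_allclose(m, means[0], rtol=1e-10)


def test_mean_rejects_empty():
    with pytest.raises(CompositionError, match="empty"):
        compositional_mean([])


# ---------------------------------------------------------------------------
# variation matrix
# ---------------------------------------------------------------------------

def test_variation_zero_for_identical_samples():
    c = close(MEAN_DAY, 1440, PARTS)
    vm = variation_matrix([c, c, c])
    np.testing.assert_allclose(vm.entries, 0.0, atol=1e-12)


def test_variation_matches_brute_force_oracle(rng):
    X = rng.lognormal(size=(7, 4), sigma=0.5) * [500, 480, 300, 30]
    vm = variation_matrix(X, PARTS)
    for i in range(4):
        for j in range(4):
            expected = np.var(np.log(X[:, i] / X[:, j]), ddof=1)
            assert vm.entries[i, j] == pytest.approx(expected, rel=1e-9, abs=1e-12)
    assert vm.entries[0, 0] == 0.0
    np.testing.assert_allclose(vm.entries, vm.entries.T, atol=0)


def test_variation_closure_invariant(rng):
    X = rng.lognormal(size=(20, 4), sigma=0.5) * [500, 480, 300, 30]
    closed = X * (1440 / X.sum(axis=1, keepdims=True))
    np.testing.assert_allclose(variation_matrix(X, PARTS).entries,
                               variation_matrix(closed, PARTS).entries, rtol=1e-9)


def test_variation_permutation_equivariant(rng):
    X = rng.lognormal(size=(20, 4), sigma=0.5) * [500, 480, 300, 30]
    perm = [2, 0, 3, 1]
    vm = variation_matrix(X, PARTS).entries
    vm_p = variation_matrix(X[:, perm], tuple(PARTS[i] for i in perm)).entries
    np.testing.assert_allclose(vm_p, vm[np.ix_(perm, perm)], rtol=1e-10)


def test_variation_perturbation_invariant(rng):
    X = rng.lognormal(size=(20, 4), sigma=0.5) * [500, 480, 300, 30]
    p = np.array([2.0, 0.5, 3.0, 0.1])
    np.testing.assert_allclose(variation_matrix(X * p, PARTS).entries,
                               variation_matrix(X, PARTS).entries, rtol=1e-9)


def test_variation_requires_two_samples():
    with pytest.raises(CompositionError, match="two"):
        variation_matrix([close(MEAN_DAY, 1440, PARTS)])


# ---------------------------------------------------------------------------
# variation <-> log-ratio covariance
# ---------------------------------------------------------------------------

def test_zero_variation_gives_zero_covariance(bases):
    cov = variation_to_lr_covariance(np.zeros((4, 4)), bases[0])
    np.testing.assert_allclose(cov, 0.0, atol=1e-15)


def test_variation_covariance_round_trip_on_target(bases):
    for sbp in bases:
        cov = variation_to_lr_covariance(TARGET_VARIATION, sbp)
        back = lr_covariance_to_variation(cov, sbp)
        np.testing.assert_allclose(back.entries, TARGET_VARIATION, atol=1e-9)


def test_variation_covariance_round_trip_simulated(rng, bases):
    X = rng.lognormal(size=(60, 4), sigma=0.5) * [500, 480, 300, 30]
    vm = variation_matrix(X, PARTS)
    for sbp in bases:
        back = lr_covariance_to_variation(
            variation_to_lr_covariance(vm, sbp), sbp)
        np.testing.assert_allclose(back.entries, vm.entries, rtol=1e-9, atol=1e-12)


def test_variation_to_covariance_validates():
    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(CompositionError, match="symmetric"):
        variation_to_lr_covariance(bad, SequentialBinaryPartition.pivot(("a", "b")))


# ---------------------------------------------------------------------------
# zero handling and the sklearn transformer
# ---------------------------------------------------------------------------

def test_replace_zeros_preserves_total_and_warns(caplog):
    with caplog.at_level("WARNING"):
        out = replace_zeros(np.array([0.0, 700.0, 740.0]), delta=0.5)
    assert out[0] == 0.5
    assert out.sum() == pytest.approx(1440.0)
    assert "replaced" in caplog.text


def test_ilr_transformer_sklearn_api(rng):
    from sklearn.base import clone

    X = rng.lognormal(size=(10, 4), sigma=0.3) * [500, 480, 300, 30]
    tr = IlrTransformer(parts=PARTS)
    Z = tr.fit_transform(X)
    assert Z.shape == (10, 3)
    sbp = SequentialBinaryPartition.pivot(PARTS)
    np.testing.assert_allclose(Z[0], ilr(X[0], sbp).values, rtol=1e-12)
    back = tr.inverse_transform(Z)
    np.testing.assert_allclose(back, X * (1440 / X.sum(axis=1, keepdims=True)),
                               rtol=1e-9)
    tr2 = clone(tr)
    assert tr2.get_params()["zero_policy"] == "error"
    with pytest.raises(CompositionError):
        tr.transform(np.array([[1.0, 0.0, 1.0, 1.0]]))
    Z0 = IlrTransformer(parts=PARTS, zero_policy="replace").fit_transform(
        np.array([[500.0, 0.0, 300.0, 30.0]]))
    assert np.all(np.isfinite(Z0))
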