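"""SFA/ICA primitives against closed forms and brute-force eigen-oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slowplace.sfa import (
    SignalBatch,
    apply_sfa,
    delta_value,
    expanded_dim,
    fit_ica,
    fit_sfa,
    quadratic_expand,
)


def brute_force_sfa(x, dt=1.0):
    """Independent oracle: explicit whitening + eigendecomposition of the
    derivative covariance (well-conditioned inputs only)."""
    xc = x - x.mean(0)
    c = xc.T @ xc / len(xc)
    d, u = np.linalg.eigh(c)
    w = u / np.sqrt(d)
    z = xc @ w
    dz = np.diff(z, axis=0) / dt
    cd = dz.T @ dz / len(dz)
    ev, evec = np.linalg.eigh(cd)
    return ev, w @ evec


class TestQuadraticExpand:
    def test_two_dim_enumeration(self):
        out = quadratic_expand(np.array([2.0, 3.0]))
        assert np.array_equal(out, [2, 3, 4, 6, 9])

    @pytest.mark.parametrize("n,expected", [(2, 5), (3, 9), (80, 3320)])
    def test_output_length_formula(self, n, expected):
        assert expanded_dim(n) == expected
        assert quadratic_expand(np.ones(n)).shape == (expected,)

    def test_monomial_enumeration_oracle(self):
        """Every product x_i x_j with i <= j appears exactly once (n=80)."""
        n = 80
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        out = quadratic_expand(x)
        products = sorted(x[i] * x[j] for i in range(n) for j in range(i, n))
        assert np.allclose(sorted(out[n:]), products)

    def test_batch_shape(self):
        x = np.zeros((7, 4, 3))
        assert quadratic_expand(x).shape == (7, 4, 9)


class TestDeltaValue:
    def test_constant_series_is_zero(self):
        assert delta_value(np.ones(100)) == 0.0

    def test_alternating_series(self):
        y = np.tile([1.0, -1.0], 50)
        assert delta_value(y, dt=1.0) == pytest.approx(4.0)

    def test_cosine_against_closed_form(self):
        t_len = 1000
        t = np.arange(t_len)
        y = np.sqrt(2) * np.cos(2 * np.pi * t / t_len)
        got = delta_value(y, dt=1.0)
        w = 2 * np.pi / t_len
        # forward difference of cos: derivative magnitude ~ w * sin
        s = np.sqrt(2) * np.sin(w * (t[:-1] + 0.5))
        expected = np.mean((2 * np.sin(w / 2) * s) ** 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2 * w**2 * np.mean(np.sin(w * t) ** 2), rel=0.01)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            delta_value(np.array([1.0]))


class TestFitSfa:
    def test_slower_sinusoid_recovered_from_mixture(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        s = np.stack([np.sqrt(2) * np.cos(t), np.sqrt(2) * np.cos(5 * t)], axis=1)
        x = s @ np.array([[1.3, 0.4], [-0.7, 2.1]]).T
        model = fit_sfa(SignalBatch(x), k=2)
        y = model.transform(x)
        assert abs(np.corrcoef(y[:, 0], s[:, 0])[0, 1]) > 0.99

    def test_constraint_triple_on_training_data(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=(500, 4)), axis=0)
        model = fit_sfa(SignalBatch(x), k=4, expansion="quadratic")
        y = model.transform(x)
        assert np.abs(y.mean(0)).max() < 1e-6
        assert np.abs(y.var(0) - 1).max() < 1e-6
        c = np.corrcoef(y.T) - np.eye(4)
        assert np.abs(c).max() < 1e-6

    def test_matches_brute_force_eigen_oracle(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(size=(2000, 6)), axis=0)
        x += 0.1 * rng.normal(size=x.shape)
        model = fit_sfa(SignalBatch(x), k=6)
        ev, proj = brute_force_sfa(x)
        assert np.abs(model.delta_values - ev).max() < 1e-8
        y_model = model.transform(x)
        y_oracle = (x - x.mean(0)) @ proj
        # same subspaces up to sign per component
        corr = np.abs(np.corrcoef(y_model.T, y_oracle.T)[:6, 6:])
        assert np.abs(np.diag(corr) - 1).max() < 1e-8

    def test_prewhitened_input_gives_signed_permutation(self):
        rng = np.random.default_rng(5)
        slow = np.cumsum(rng.normal(size=1000))
        slow = (slow - slow.mean()) / slow.std()
        fast = rng.normal(size=1000)
        fast = (fast - fast.mean()) / fast.std()
        fast -= slow * (slow @ fast) / (slow @ slow)
        fast /= fast.std()
        x = np.stack([fast, slow], axis=1)
        model = fit_sfa(SignalBatch(x), k=2)
        # projection should be close to a signed permutation (slow first)
        p = np.abs(model.projection)
        assert p[1, 0] > 10 * p[0, 0]
        assert p[0, 1] > 10 * p[1, 1]

    def test_delta_values_ascending(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.normal(size=(800, 5)), axis=0)
        model = fit_sfa(SignalBatch(x), k=5, expansion="quadratic")
        assert np.all(np.diff(model.delta_values) >= -1e-12)

    def test_refit_reproduces_identical_projection(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.normal(size=(400, 3)), axis=0)
        a = fit_sfa(SignalBatch(x), k=3, expansion="quadratic")
        b = fit_sfa(SignalBatch(x), k=3, expansion="quadratic")
        assert np.array_equal(a.projection, b.projection)

    def test_k_exceeding_rank_rejected(self):
        x = np.outer(np.arange(100.0), np.ones(3))  # rank-1 data
        with pytest.raises(ValueError):
            fit_sfa(SignalBatch(x), k=3)

    def test_spatial_harmonic_recovery_from_slow_walk(self):
        """Quadratic SFA on a slow 2-D walk in a rectangle yields the
        half-period spatial cosines (the theoretical open-field code)."""
        rng = np.random.default_rng(8)
        n = 20000
        lx, ly = 2.0, 1.0
        pos = np.empty((n, 2))
        p = np.array([1.0, 0.5])
        for i in range(n):
            p = p + rng.normal(scale=[0.02, 0.014])
            p[0] = np.clip(p[0], 0, lx)
            p[1] = np.clip(p[1], 0, ly)
            pos[i] = p
        model = fit_sfa(SignalBatch(pos), k=3, expansion="quadratic")
        y = model.transform(pos)
        c1 = np.cos(np.pi * pos[:, 0] / lx)
        c2 = np.cos(np.pi * pos[:, 1] / ly)
        assert abs(np.corrcoef(y[:, 0], c1)[0, 1]) > 0.9
        assert abs(np.corrcoef(y[:, 1], c2)[0, 1]) > 0.9


class TestApplySfa:
    def test_training_batch_constraints_restated(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        model = fit_sfa(SignalBatch(x), k=3)
        y = apply_sfa(model, SignalBatch(x)).values
        assert np.abs(y.mean(0)).max() < 1e-6

    def test_constant_input_gives_constant_output(self):
        rng = np.random.default_rng(10)
        x = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        model = fit_sfa(SignalBatch(x), k=2)
        const = np.tile(x[0], (50, 1))
        y = model.transform(const)
        assert np.abs(y - y[0]).max() < 1e-12

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        x = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        model = fit_sfa(SignalBatch(x), k=2)
        with pytest.raises(ValueError):
            model.transform(np.zeros((10, 5)))


class TestFitIca:
    def test_laplacian_sources_recovered(self):
        rng = np.random.default_rng(0)
        s = rng.laplace(size=(5000, 2))
        x = s @ np.array([[0.8, 0.6], [-0.6, 0.8]]).T
        model = fit_ica(SignalBatch(x), n_components=2, seed=1)
        y = model.transform(x)
        corr = np.abs(np.corrcoef(y.T, s.T)[:2, 2:])
        assert corr.max(axis=1).min() > 0.95

    def test_outputs_decorrelated_unit_variance(self):
        rng = np.random.default_rng(1)
        s = rng.laplace(size=(4000, 4))
        x = s @ rng.normal(size=(4, 4))
        model = fit_ica(SignalBatch(x), n_components=4, seed=2)
        y = model.transform(x)
        c = y.T @ y / len(y)
        assert np.abs(c - np.eye(4)).max() < 0.05

    def test_sign_convention_largest_value_positive(self):
        rng = np.random.default_rng(2)
        s = rng.laplace(size=(3000, 3))
        x = s @ rng.normal(size=(3, 3))
        model = fit_ica(SignalBatch(x), n_components=3, seed=3)
        y = model.transform(x)
        peaks = np.abs(y).argmax(axis=0)
        assert np.all(y[peaks, np.arange(3)] > 0)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_ica(SignalBatch(np.random.default_rng(0).normal(size=(100, 2))),
                    n_components=5)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=12))
    def test_expansion_dimension_invariant(self, n):
        assert len(quadratic_expand(np.ones(n))) == n + n * (n + 1) // 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_delta_nonnegative(self, seed):
        y = np.random.default_rng(seed).normal(size=50)
        assert delta_value(y) >= 0.0
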