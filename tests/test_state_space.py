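import numpy as np
import pytest

from conftest import lds_brute_force
from srtlearn.exceptions import DegenerateInputError
from srtlearn.state_space import (
    LdsParams,
    build_inputs,
    default_init,
    em_fit,
    kalman_smooth,
    lds_predict_observe,
    simulate_lds,
)
from srtlearn.task_model import canonical_sequence


def _params(**kw):
    base = dict(
        a=0.7,
        b=np.zeros(8),
        d=np.zeros(8),
        f=0.0,
        q=25.0,
        r=100.0,
        x1_mean=0.0,
        x1_var=50.0,
    )
    base.update(kw)
    return LdsParams(**base)


def _onehot(k):
    v = np.zeros(8)
    v[k - 1] = 1.0
    return v


class TestPredictObserve:
    def test_output_reduces_to_bias_without_state(self):
        d = np.zeros(8)
        d[2] = 310.0
        p = _params(a=0.0, d=d)
        _, y = lds_predict_observe(p, 0.0, _onehot(3), np.zeros(8), 0.0)
        assert y == pytest.approx(310.0)

    def test_pure_state_retention(self):
        p = _params(a=0.8)
        x_next, _ = lds_predict_observe(p, -10.0, _onehot(1), np.zeros(8), 0.0)
        assert x_next == pytest.approx(-8.0)

    def test_error_delays_next_state_by_f(self):
        p = _params(a=1.0, f=15.0)
        x_next, _ = lds_predict_observe(p, 0.0, _onehot(1), np.zeros(8), 1.0)
        assert x_next == pytest.approx(15.0)

    def test_previous_press_feeds_through_b(self):
        b = np.zeros(8)
        b[4] = -6.0
        p = _params(a=0.0, b=b)
        x_next, _ = lds_predict_observe(p, 99.0, _onehot(1), _onehot(5), 0.0)
        assert x_next == pytest.approx(-6.0)


class TestKalmanSmoother:
    def _random_problem(self, seed, n=20, missing=True):
        rng = np.random.default_rng(seed)
        cues = rng.integers(1, 9, n)
        errs = (rng.random(n) < 0.2).astype(float)
        params = _params(
            a=0.6 + 0.2 * rng.random(),
            b=rng.normal(0, 2, 8),
            d=rng.normal(300, 20, 8),
            f=12.0,
            q=25.0,
            r=80.0,
        )
        y, inputs, _ = simulate_lds(params, cues, errs, seed=seed + 1)
        if missing:
            y[rng.integers(n)] = np.nan
        return params, y, inputs

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_joint_gaussian_oracle(self, seed):
        """Exact agreement with the explicit joint-normal conditional (n = 20)."""
        params, y, inputs = self._random_problem(seed)
        tr = kalman_smooth(params, y, inputs)
        m_o, v_o, ll_o = lds_brute_force(params, y, inputs)
        np.testing.assert_allclose(tr.smoothed_means, m_o, atol=1e-8)
        np.testing.assert_allclose(tr.smoothed_vars, v_o, atol=1e-8)
        assert tr.loglik == pytest.approx(ll_o, abs=1e-8)

    def test_noiseless_limit_recovers_deterministic_recursion(self):
        p = _params(a=0.9, q=0.0, r=1e-8, x1_mean=20.0, x1_var=0.0)
        n = 15
        cues = np.ones(n, dtype=int)
        inputs = build_inputs(cues, cues, np.zeros(n))
        truth = 20.0 * 0.9 ** np.arange(n)
        tr = kalman_smooth(p, truth.copy(), inputs)
        np.testing.assert_allclose(tr.smoothed_means, truth, atol=1e-5)

    def test_singular_innovation_rejected(self):
        p = _params(q=0.0, r=0.0, x1_var=0.0)
        n = 5
        cues = np.ones(n, dtype=int)
        inputs = build_inputs(cues, cues, np.zeros(n))
        with pytest.raises(DegenerateInputError):
            kalman_smooth(p, np.array([1.0, 2.0, 3.0, 4.0, 5.0]), inputs)

    def test_smoothed_state_tracks_truth(self):
        """At Q/R = 1 the smoothed state correlates with the latent truth."""
        rs = []
        for seed in range(10):
            params = _params(a=0.8, q=50.0, r=50.0, x1_var=50.0 / (1 - 0.64))
            rng = np.random.default_rng(100 + seed)
            cues = rng.integers(1, 9, 224)
            errs = (rng.random(224) < 0.1).astype(float)
            y, inputs, x = simulate_lds(params, cues, errs, seed=seed)
            tr = kalman_smooth(params, y, inputs)
            rs.append(np.corrcoef(tr.smoothed_means, x)[0, 1])
        assert np.mean(rs) > 0.7


class TestEmFit:
    def test_loglik_non_decreasing(self):
        for seed in (0, 5):
            rng = np.random.default_rng(seed)
            cues = rng.integers(1, 9, 300)
            errs = (rng.random(300) < 0.15).astype(float)
            true = _params(a=0.5, f=10.0, q=30.0, r=60.0, d=rng.normal(0, 15, 8))
            y, inputs, _ = simulate_lds(true, cues, errs, seed=seed + 7)
            res = em_fit(y, inputs, max_iter=60)
            diffs = np.diff(res.loglik_path)
            assert (diffs >= -1e-8 * (np.abs(res.loglik_path[:-1]) + 1.0)).all()

    def test_recovers_a_and_f(self):
        """Parameter recovery at the probe-block scale (scaled-down seeds)."""
        seq = canonical_sequence()
        a_hats, f_hats = [], []
        true = LdsParams(
            a=0.5, b=np.zeros(8), d=np.linspace(-20, 20, 8), f=15.0,
            q=25.0, r=100.0, x1_mean=0.0, x1_var=25.0 / (1 - 0.25),
        )
        for seed in range(6):
            rng = np.random.default_rng(500 + seed)
            blocks = []
            for _ in range(8):
                cues = seq.cues_for_block(int(rng.integers(32)))
                errs = (rng.random(256) < 0.1).astype(float)
                yb, ib, _ = simulate_lds(true, cues, errs, seed=int(rng.integers(2**31 - 1)))
                blocks.append((yb, ib))
            res = em_fit(blocks, max_iter=80)
            a_hats.append(res.params.a)
            f_hats.append(res.params.f)
        assert abs(np.median(a_hats) - 0.5) < 0.1
        assert abs(np.median(f_hats) - 15.0) < 5.0

    def test_null_dynamics_shrink_a(self):
        """With A = B = F = 0 in truth, the fitted A stays near zero."""
        hits = 0
        true = _params(a=0.0, f=0.0, q=25.0, r=100.0, x1_var=25.0)
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            blocks = []
            for _ in range(6):
                cues = rng.integers(1, 9, 256)
                errs = (rng.random(256) < 0.1).astype(float)
                yb, ib, _ = simulate_lds(true, cues, errs, seed=int(rng.integers(2**31 - 1)))
                blocks.append((yb, ib))
            res = em_fit(blocks, max_iter=60)
            hits += abs(res.params.a) < 0.1
        assert hits >= 9

    def test_d_ordering_recovered(self):
        """The across-key ordering of the response bias D survives the fit."""
        seq = canonical_sequence()
        true = LdsParams(
            a=0.4, b=np.zeros(8), d=np.linspace(-30, 30, 8), f=10.0,
            q=25.0, r=64.0, x1_mean=0.0, x1_var=25.0 / (1 - 0.16),
        )
        rng = np.random.default_rng(77)
        blocks = []
        for _ in range(6):
            cues = seq.cues_for_block(int(rng.integers(32)))
            errs = (rng.random(256) < 0.1).astype(float)
            yb, ib, _ = simulate_lds(true, cues, errs, seed=int(rng.integers(2**31 - 1)))
            blocks.append((yb, ib))
        res = em_fit(blocks, max_iter=80)
        from scipy.stats import spearmanr

        rho = spearmanr(res.params.d, true.d).statistic
        assert rho > 0.9


class TestSimulateLds:
    def test_deterministic_given_seed(self):
        p = _params(d=np.full(8, 300.0))
        cues = np.tile(np.arange(1, 9), 10)
        errs = np.zeros(80)
        y1, _, _ = simulate_lds(p, cues, errs, seed=3)
        y2, _, _ = simulate_lds(p, cues, errs, seed=3)
        np.testing.assert_array_equal(y1, y2)

    def test_noiseless_simulation_follows_chained_means(self):
        p = _params(a=0.8, f=15.0, q=0.0, r=0.0, x1_mean=5.0, x1_var=0.0,
                    d=np.full(8, 300.0))
        cues = np.ones(10, dtype=int)
        errs = np.zeros(10)
        errs[3] = 1.0
        y, inputs, x = simulate_lds(p, cues, errs, seed=0)
        xs = [5.0]
        for t in range(1, 10):
            xs.append(0.8 * xs[-1] + 15.0 * errs[t - 1])
        np.testing.assert_allclose(x, xs, atol=1e-12)
        np.testing.assert_allclose(y, np.array(xs) + 300.0, atol=1e-12)

    def test_default_init_uses_per_key_means(self):
        rng = np.random.default_rng(1)
        cues = rng.integers(1, 9, 400)
        d_true = np.linspace(280, 350, 8)
        y = d_true[cues - 1] + rng.normal(0, 5, 400)
        inputs = build_inputs(cues, cues, np.zeros(400))
        init = default_init([(y, inputs)])
        np.testing.assert_allclose(init.d, d_true, atol=2.0)
        assert init.x1_var == pytest.approx(10 * init.q)
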