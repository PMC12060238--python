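"""Sampler kernels, run schedule, determinism, diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ploidymc import (
    ChainConfig,
    CountMatrix,
    convergence_report,
    propose_lambda,
    reflect,
    rescale_weights,
    run_chain,
    run_chains,
)
from ploidymc.errors import ValidationError


class TestReflect:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.3, 0.3), (0.0, 0.0), (1.0, 1.0), (1.2, 0.8), (-0.3, 0.3), (2.5, 0.5)],
    )
    def test_known_values(self, x, expected):
        assert reflect(x) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6))
    def test_range_and_idempotence(self, x):
        y = reflect(x)
        assert 0.0 <= y <= 1.0
        assert reflect(y) == y


class TestLambdaProposal:
    def test_forced_value_two_chromosomes(self):
        np.testing.assert_allclose(
            rescale_weights(np.array([0.5, 0.5]), 0, 0.6), [0.6, 0.4]
        )

    def test_forced_value_three_chromosomes(self):
        np.testing.assert_allclose(
            rescale_weights(np.array([0.2, 0.3, 0.5]), 0, 0.4), [0.4, 0.225, 0.375]
        )

    def test_rescale_preserves_simplex(self):
        lam = np.array([0.1, 0.2, 0.3, 0.4])
        out = rescale_weights(lam, 2, 0.05)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_proposal_stays_on_simplex(self):
        rng = np.random.default_rng(7)
        lam = np.array([0.2, 0.3, 0.5])
        for _ in range(200):
            lam = propose_lambda(lam, int(rng.integers(3)), 100.0, rng)
            assert lam.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((lam > 0) & (lam < 1))


@pytest.fixture(scope="module")
def small_counts():
    rng = np.random.default_rng(11)
    lam = np.array([0.25, 0.35, 0.4])
    k = np.array([[6, 6, 6], [6, 7, 6], [6, 6, 5]])
    counts = np.stack(
        [rng.multinomial(50_000, lam * ki / (lam * ki).sum()) for ki in k]
    )
    return CountMatrix(counts, ("A", "B", "C"), ("c1", "c2", "c3")), k


class TestRunChain:
    def test_identical_seed_identical_trace(self, small_counts):
        cm, _ = small_counts
        cfg = ChainConfig(iterations=500, burn_in=100, seed=5, n_chains=1)
        t1 = run_chain(cm, cfg)
        t2 = run_chain(cm, cfg)
        np.testing.assert_array_equal(t1.p_samples, t2.p_samples)
        np.testing.assert_array_equal(t1.lambda_samples, t2.lambda_samples)
        np.testing.assert_array_equal(t1.k_samples, t2.k_samples)

    def test_simplex_conserved_throughout(self, small_counts):
        cm, _ = small_counts
        cfg = ChainConfig(iterations=800, burn_in=0, seed=2, n_chains=1)
        trace = run_chain(cm, cfg)
        sums = trace.lambda_samples.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert np.all((trace.lambda_samples > 0) & (trace.lambda_samples < 1))

    def test_fix_flags_hold_parameters_constant(self, small_counts):
        cm, _ = small_counts
        lam = np.array([0.3, 0.3, 0.4])
        cfg = ChainConfig(
            iterations=300, burn_in=50, seed=3, n_chains=1, fix_lambda=lam, fix_p=0.25
        )
        trace = run_chain(cm, cfg)
        assert np.all(trace.p_samples == 0.25)
        np.testing.assert_array_equal(
            trace.lambda_samples, np.tile(lam, (trace.n_recorded, 1))
        )

    def test_posterior_counts_match_draws(self, small_counts):
        cm, _ = small_counts
        cfg = ChainConfig(iterations=400, burn_in=100, seed=4, n_chains=1)
        trace = run_chain(cm, cfg)
        for i in range(cm.n_samples):
            for j in range(cm.n_chromosomes):
                hist = np.bincount(trace.k_samples[:, i, j], minlength=13)
                np.testing.assert_array_equal(hist, trace.k_posterior_counts[i, j])

    def test_twelve_to_zero_wraparound_is_reachable(self):
        """On the 13-cycle, state 0 neighbors state 12: with no data the
        chain must cross the 12-0 edge."""
        cm = CountMatrix(np.zeros((1, 2), dtype=int), ("s",), ("c1", "c2"))
        cfg = ChainConfig(
            iterations=4000, burn_in=0, seed=0, n_chains=1,
            fix_lambda=np.array([0.5, 0.5]), fix_p=0.0,
        )
        trace = run_chain(cm, cfg)
        ks = trace.k_samples[:, 0, 0].astype(int)
        transitions = set(zip(ks[:-1], ks[1:]))
        assert (12, 0) in transitions or (0, 12) in transitions

    def test_thinning_controls_record_count(self, small_counts):
        cm, _ = small_counts
        cfg = ChainConfig(iterations=1000, burn_in=200, thin=5, seed=1, n_chains=1)
        assert run_chain(cm, cfg).n_recorded == 160

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValidationError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ValidationError):
            ChainConfig(rate_lambda=-1.0)


@pytest.fixture(scope="module")
def wide_counts():
    """10 samples x 6 chromosomes, deep enough to pin every mode and
    wide enough to suppress whole-row metastability."""
    rng = np.random.default_rng(11)
    lam = rng.dirichlet(np.full(6, 20.0))
    k = np.full((10, 6), 6)
    k[1, 1] = 7
    k[2, 5] = 5
    counts = np.stack(
        [rng.multinomial(30_000, lam * ki / (lam * ki).sum()) for ki in k]
    )
    return CountMatrix(
        counts, tuple(f"s{i}" for i in range(10)), tuple(f"c{j}" for j in range(6))
    )


class TestConvergenceReport:
    def _trace(self, cm, seed, iterations=3000, **kw):
        # step sizes matched to the tight posterior of this deep toy
        kw.setdefault("rate_lambda", 1000.0)
        kw.setdefault("rate_p", 20.0)
        cfg = ChainConfig(
            iterations=iterations, burn_in=iterations // 5, seed=seed,
            n_chains=1, store_k_draws=False, **kw,
        )
        return run_chain(cm, cfg)

    def test_identical_chains_give_exactly_one(self, wide_counts):
        t = self._trace(wide_counts, 9)
        report = convergence_report([t, t])
        assert (report.table["psrf"] == 1.0).all()
        assert report.mode_agreement == 1.0

    def test_well_identified_toy_converges(self, wide_counts):
        traces = [self._trace(wide_counts, s, iterations=8000) for s in (10, 11)]
        report = convergence_report(traces)
        assert report.table["psrf"].max() < 1.1
        assert report.mode_agreement == 1.0
        assert report.converged

    def test_divergent_chains_flagged(self, wide_counts):
        good = self._trace(wide_counts, 12)
        # fabricate divergence: pin one chain's lambda off-truth with a
        # near-point-mass prior so its k modes stay at 6
        stuck = self._trace(
            wide_counts, 12,
            fix_lambda=np.array([0.4, 0.2, 0.1, 0.1, 0.1, 0.1]), fix_p=0.9999,
        )
        report = convergence_report([good, stuck])
        assert report.table["psrf"].max() > 1.1
        assert not report.converged

    def test_unequal_lengths_rejected(self, wide_counts):
        a = self._trace(wide_counts, 1)
        b = self._trace(wide_counts, 2, iterations=2000)
        with pytest.raises(ValidationError, match="unequal"):
            convergence_report([a, b])

    def test_single_chain_rejected(self, wide_counts):
        with pytest.raises(ValidationError, match="two chains"):
            convergence_report([self._trace(wide_counts, 1)])


def test_multi_chain_seeds_differ(small_counts):
    cm, _ = small_counts
    cfg = ChainConfig(iterations=400, burn_in=100, seed=21, n_chains=2)
    t0, t1 = run_chains(cm, cfg)
    assert t0.seed == 21 and t1.seed == 22
    assert not np.array_equal(t0.p_samples, t1.p_samples)
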