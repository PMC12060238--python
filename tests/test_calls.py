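"""Posterior calling, cohort tables, Fisher's exact test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from ploidymc import (
    ChainConfig,
    CountMatrix,
    SampleMetadata,
    cohort_tables,
    fisher_exact,
    fisher_exact_exhaustive,
    run_chain,
    summarize_posterior,
)
from ploidymc.errors import DomainError, ValidationError
from ploidymc.mcmc import ChainTrace


def _trace_from_pmf(pmfs):
    """Fabricate a one-sample trace whose posterior counts realize the
    given per-chromosome pmfs (scaled to 10,000 draws)."""
    pmfs = np.asarray(pmfs)
    m = pmfs.shape[0]
    counts = np.round(pmfs * 10_000).astype(np.int64)[np.newaxis, :, :]
    cfg = ChainConfig(iterations=10, burn_in=0, n_chains=1)
    return ChainTrace(
        p_samples=np.zeros(10),
        lambda_samples=np.full((10, m), 1 / m),
        k_posterior_counts=counts,
        loglik_samples=np.zeros(10),
        k_samples=None,
        acceptance_rates={},
        seed=0,
        sample_ids=("s1",),
        chromosomes=tuple(f"c{j}" for j in range(m)),
        config=cfg,
    )


def _pmf(**kv):
    v = np.zeros(13)
    for k, p in kv.items():
        v[int(k[1:])] = p
    return v


class TestSummarizePosterior:
    def test_call_rule(self):
        trace = _trace_from_pmf(
            [
                _pmf(k7=0.99, k6=0.01),  # confident gain
                _pmf(k6=0.99, k7=0.01),  # euploid
                _pmf(k7=0.55, k6=0.45),  # below threshold -> uncertain
                _pmf(k5=0.97, k6=0.03),  # confident loss
            ]
        )
        calls = summarize_posterior(trace, min_prob=0.95)
        assert list(calls["call"]) == ["gain", "euploid", "uncertain", "loss"]
        assert list(calls["mode"]) == [7, 6, 7, 5]

    def test_pmf_columns_sum_to_one(self):
        trace = _trace_from_pmf([_pmf(k6=0.7, k7=0.3)])
        calls = summarize_posterior(trace)
        pmf_cols = [f"pmf_{k}" for k in range(13)]
        np.testing.assert_allclose(calls[pmf_cols].sum(axis=1), 1.0)

    def test_tie_between_five_and_seven_resolves_low(self):
        trace = _trace_from_pmf([_pmf(k5=0.5, k7=0.5)])
        assert summarize_posterior(trace)["mode"].iloc[0] == 5

    def test_tie_including_baseline_resolves_to_baseline(self):
        trace = _trace_from_pmf([_pmf(k6=0.5, k7=0.5)])
        assert summarize_posterior(trace)["call"].iloc[0] == "euploid"

    def test_empty_trace_rejected(self):
        trace = _trace_from_pmf([np.zeros(13)])
        with pytest.raises(ValidationError, match="empty trace"):
            summarize_posterior(trace)


def _calls_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "call"]).assign(
        mode=lambda d: d["call"].map({"gain": 7, "loss": 5}).fillna(6),
        mode_prob=1.0,
    )


class TestCohortTables:
    def test_percent_aneuploids_total_tree_denominator(self):
        # 11 aneuploid samples among 82
        meta = [SampleMetadata(f"v{i}", "vegetative") for i in range(82)]
        rows = [(f"v{i}", "chr1", "loss") for i in range(9)]
        rows += [(f"v{i}", "chr8", "gain") for i in range(9, 11)]
        rows += [(f"v{i}", "chr2", "euploid") for i in range(11, 82)]
        table = cohort_tables(_calls_df(rows), meta)
        assert table.summary.loc["percent_aneuploids", "vegetative"] == pytest.approx(
            13.4146, abs=1e-4
        )
        assert table.summary.loc["total_aneuploids", "vegetative"] == 11
        assert table.summary.loc["no_aneuploidy", "vegetative"] == 71

    def test_zero_aneuploids_percent_zero(self):
        meta = [SampleMetadata(f"o{i}", "old_growth") for i in range(5)]
        rows = [(f"o{i}", "chr1", "euploid") for i in range(5)]
        table = cohort_tables(_calls_df(rows), meta)
        assert table.summary.loc["percent_aneuploids", "old_growth"] == 0.0

    def test_per_chromosome_gain_counting(self):
        meta = [
            SampleMetadata("s1", "second_growth"),
            SampleMetadata("s2", "second_growth"),
        ]
        rows = [("s1", "chr10", "gain"), ("s2", "chr10", "gain")]
        table = cohort_tables(_calls_df(rows), meta)
        assert table.per_chromosome.loc["chr10", ("second_growth", "ploidy7")] == 2

    def test_count_conservation_across_chromosomes(self):
        meta = [SampleMetadata(f"s{i}", "second_growth") for i in range(6)]
        rows = [
            ("s0", "chr1", "gain"), ("s1", "chr2", "gain"), ("s2", "chr3", "loss"),
            ("s3", "chr1", "euploid"), ("s4", "chr2", "uncertain"),
            ("s5", "chr4", "loss"),
        ]
        table = cohort_tables(_calls_df(rows), meta)
        per_chrom = table.per_chromosome["second_growth"]
        assert per_chrom["ploidy7"].sum() == table.summary.loc[
            "gain_of_chromosome", "second_growth"
        ]
        assert per_chrom["ploidy5"].sum() == table.summary.loc[
            "loss_of_chromosome", "second_growth"
        ]
        s = table.summary["second_growth"]
        assert (
            s["loss_of_chromosome"] + s["gain_of_chromosome"] == s["total_aneuploids"]
        )

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError, match="without metadata"):
            cohort_tables(_calls_df([("ghost", "chr1", "gain")]), [])


class TestFisherExact:
    def test_loss_contingency_matches_published_value(self):
        assert fisher_exact([[1, 273], [9, 73]]) == pytest.approx(1.039e-5, rel=5e-3)

    def test_stand_age_contingency_matches_published_value(self):
        assert fisher_exact([[0, 56], [9, 209]]) == pytest.approx(0.21, abs=0.005)

    def test_no_association_gives_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0, abs=1e-12)

    def test_one_sided_tails(self):
        assert fisher_exact([[0, 56], [9, 209]], sided="less") == pytest.approx(
            0.12, abs=0.01
        )
        assert fisher_exact([[0, 56], [9, 209]], sided="greater") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact([[0, 0], [0, 0]])

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_agrees_with_exact_rational_enumeration(self, a, b, c, d):
        """Float implementation vs Fraction-arithmetic enumeration over
        all margin-preserving tables."""
        if a + b + c + d == 0:
            return
        t = [[a, b], [c, d]]
        for sided in ("two_sided_min_likelihood", "less", "greater"):
            exact = float(fisher_exact_exhaustive(t, sided))
            assert fisher_exact(t, sided) == pytest.approx(exact, rel=1e-9, abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_agrees_with_scipy_and_bounds(self, a, b, c, d):
        """Cross-check against scipy's independent implementation;
        two-sided >= best one-sided; p in (0, 1]."""
        if a + b + c + d == 0:
            return
        t = [[a, b], [c, d]]
        two = fisher_exact(t)
        assert two == pytest.approx(scipy.stats.fisher_exact(t)[1], rel=1e-7)
        less = fisher_exact(t, "less")
        greater = fisher_exact(t, "greater")
        assert two >= min(less, greater) - 1e-12
        for p in (two, less, greater):
            assert 0.0 < p <= 1.0
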