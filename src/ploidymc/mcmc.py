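"""Metropolis–Hastings sampler over (lambda, K, p).

One iteration cycles three kernels:

1. every ploidy cell ``k_ij`` — a symmetric +/-1 random walk on the
   circle of integers {0..12} (0 and 12 adjacent, which keeps the
   proposal symmetric at the boundary); the acceptance ratio contains
   the multinomial likelihood and the reflected-geometric prior;
2. every chromosome weight ``lambda_j`` — a reflected two-sided
   exponential step, after which the remaining coordinates are
   rescaled by (1 - lambda_j') / (1 - lambda_j) so the simplex
   constraint is preserved; with the uniform Dirichlet prior only the
   likelihood enters the ratio;
3. the prior sharpness ``p`` — the same reflected exponential step;
   the only p-dependent factor of the target is the ploidy-prior
   product, so that alone enters the ratio.

The k-sweep visits chromosomes in fixed order and updates all samples
of one chromosome as a vectorized block; given lambda and p the
samples are conditionally independent, so this is equivalent in law
to a cell-by-cell sweep while being orders of magnitude faster in
numpy.  Traces are a pure function of (counts, config): a fixed seed
reproduces a run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .errors import DomainError, InvalidStateError, ValidationError
from . import model
from .model import BASELINE_PLOIDY, N_STATES, log_k_prior_pmf

_LOG_K_SAFE = np.log(np.maximum(np.arange(N_STATES), 1).astype(float))


def reflect(x: float) -> float:
    """Fold a real into [0, 1] by repeated boundary reflection.

    Identity on [0, 1]; idempotent.  Used to keep exponential-step
    proposals for lambda_j and p inside their support while preserving
    kernel symmetry.
    """
    if not np.isfinite(x):
        raise DomainError(f"reflect requires a finite value, got {x}")
    # fold into one period first so huge arguments terminate quickly
    x = float(x) % 2.0
    while x < 0.0 or x > 1.0:
        if x < 0.0:
            x = -x
        elif x > 1.0:
            x = 2.0 - x
    return x


def rescale_weights(lam: np.ndarray, j: int, new_value: float) -> np.ndarray:
    """Set lambda_j to ``new_value`` and co-rescale the rest.

    The other coordinates are multiplied by
    (1 - new_value) / (1 - lambda_j), so the result sums to 1 exactly
    (up to float rounding).
    """
    lam = np.asarray(lam, dtype=float)
    if not 0.0 < new_value < 1.0:
        raise DomainError(f"new weight must be in (0, 1), got {new_value}")
    if not 0.0 < lam[j] < 1.0:
        raise DomainError("current weight must be in (0, 1)")
    out = lam * ((1.0 - new_value) / (1.0 - lam[j]))
    out[j] = new_value
    return out


def propose_lambda(
    lam: np.ndarray, j: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a weight proposal: reflected symmetric-exponential step on
    coordinate j, co-rescaling the rest (see :func:`rescale_weights`).

    A degenerate draw landing exactly on 0 or 1 (probability zero, but
    possible in floats) is resampled.
    """
    for _ in range(100):
        step = rng.exponential(1.0 / rate)
        sign = 1.0 if rng.integers(0, 2) == 1 else -1.0
        cand = reflect(lam[j] + sign * step)
        if 0.0 < cand < 1.0:
            return rescale_weights(lam, j, cand)
    raise DomainError("lambda proposal degenerated 100 times in a row")


@dataclass(frozen=True)
class ChainConfig:
    """Run schedule and kernel settings for one or more chains.

    ``rate_lambda`` / ``rate_p`` are the rates of the exponential step
    distributions (default 100.0, i.e. mean step 0.01).  ``fix_lambda``
    / ``fix_p`` pin those parameters (used by the exact-enumeration
    oracle and for sensitivity runs).  Chain c of a multi-chain run
    uses ``seed + c``.
    """

    iterations: int = 100_000
    burn_in: int = 10_000
    rate_lambda: float = 100.0
    rate_p: float = 100.0
    n_chains: int = 4
    seed: int = 0
    fix_lambda: np.ndarray | None = None
    fix_p: float | None = None
    thin: int = 1
    store_k_draws: bool = True
    overdispersed_start: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.burn_in >= self.iterations:
            raise ValidationError("need 0 <= burn_in < iterations")
        if self.rate_lambda <= 0 or self.rate_p <= 0:
            raise ValidationError("proposal rates must be positive")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.fix_lambda is not None:
            object.__setattr__(
                self, "fix_lambda", model.validate_weights(np.asarray(self.fix_lambda))
            )
        if self.fix_p is not None and not 0.0 <= self.fix_p <= 1.0:
            raise ValidationError("fix_p must lie in [0, 1]")

    @property
    def n_records(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class ChainTrace:
    """Post-burn-in record of one chain.

    ``k_posterior_counts[i, j, k]`` counts recorded iterations with
    ploidy state k in cell (i, j); it is always kept.  Full ploidy
    draws (``k_samples``) are optional and stored as int8.
    """

    p_samples: np.ndarray
    lambda_samples: np.ndarray
    k_posterior_counts: np.ndarray
    loglik_samples: np.ndarray
    k_samples: np.ndarray | None
    acceptance_rates: dict[str, float]
    seed: int
    sample_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    config: ChainConfig

    @property
    def n_recorded(self) -> int:
        return len(self.p_samples)

    def to_frame(self) -> pd.DataFrame:
        """Trace as a tidy table: record index, p, lambda_1..m, loglik."""
        df = pd.DataFrame(
            self.lambda_samples, columns=[f"lambda_{c}" for c in self.chromosomes]
        )
        df.insert(0, "p", self.p_samples)
        df["loglik"] = self.loglik_samples
        df.index.name = "record"
        return df


def _initial_state(
    counts: CountMatrix, config: ChainConfig, chain_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n, m = counts.counts.shape
    if config.fix_lambda is not None:
        lam = config.fix_lambda.copy()
    elif chain_index > 0 and config.overdispersed_start:
        lam = rng.dirichlet(np.ones(m))
        while np.any(lam <= 1e-12):  # avoid a degenerate start
            lam = rng.dirichlet(np.ones(m))
    else:
        total = counts.N
        if total > 0:
            col = counts.column_totals.astype(float)
            # keep strictly positive even if a chromosome has no reads
            lam = (col + 0.5) / (col + 0.5).sum()
        else:
            lam = np.full(m, 1.0 / m)
    if config.fix_p is not None:
        p = float(config.fix_p)
    elif chain_index > 0 and config.overdispersed_start:
        p = float(rng.uniform())
    else:
        p = 0.5
    k = np.full((n, m), BASELINE_PLOIDY, dtype=np.int64)
    if chain_index > 0 and config.overdispersed_start:
        k = k + rng.integers(-1, 2, size=(n, m))
    return lam, k, p


def run_chain(
    counts: CountMatrix,
    config: ChainConfig,
    chain_index: int = 0,
    progress=None,
) -> ChainTrace:
    """Run one chain; chain c uses seed ``config.seed + c``.

    ``progress``, if given, is called as ``progress(iteration, total)``
    every 1,000 iterations.

    Raises
    ------
    InvalidStateError
        If the target is non-finite at the initial state.
    """
    seed = config.seed + chain_index
    rng = np.random.default_rng(seed)
    n_counts = counts.counts
    n, m = n_counts.shape
    row_tot = counts.row_totals.astype(float)
    col_tot = counts.column_totals.astype(float)
    row_pos = row_tot > 0

    lam, k, p = _initial_state(counts, config, chain_index, rng)
    init_ll = model.log_likelihood(counts, lam, k)
    init_lp = model.log_prior_k(k, p)
    if not np.isfinite(init_ll) or not np.isfinite(init_lp):
        raise InvalidStateError(
            f"non-finite target at initialization (loglik={init_ll}, "
            f"log prior={init_lp}); check counts and starting state"
        )

    loglam = np.log(lam)
    logpmf = log_k_prior_pmf(p)
    s = (k * lam[np.newaxis, :]).sum(axis=1)  # per-sample normalizer
    logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), 0.0)

    update_lambda = config.fix_lambda is None
    update_p = config.fix_p is None

    n_rec = config.n_records
    p_samples = np.empty(n_rec)
    lambda_samples = np.empty((n_rec, m))
    loglik_samples = np.empty(n_rec)
    k_post = np.zeros((n, m, N_STATES), dtype=np.int64)
    k_draws = np.empty((n_rec, n, m), dtype=np.int8) if config.store_k_draws else None
    ii = np.arange(n)[:, np.newaxis]
    jj = np.arange(m)[np.newaxis, :]

    acc = {"k": 0, "lambda": 0, "p": 0}
    prop = {"k": 0, "lambda": 0, "p": 0}
    rec = 0

    for it in range(config.iterations):
        if progress is not None and it % 1000 == 0:
            progress(it, config.iterations)
        # --- ploidy sweep, one chromosome at a time, all samples at once
        for j in range(m):
            kcur = k[:, j]
            step = rng.integers(0, 2, size=n) * 2 - 1
            kprop = (kcur + step) % N_STATES
            nj = n_counts[:, j].astype(float)
            ds = lam[j] * (kprop - kcur)
            snew = s + ds
            bad = ((kprop == 0) & (nj > 0)) | (row_pos & (snew <= 0))
            log_snew = np.log(np.where(snew > 0, snew, 1.0))
            dloglik = nj * (_LOG_K_SAFE[kprop] - _LOG_K_SAFE[kcur]) - np.where(
                row_pos, row_tot * (log_snew - logs), 0.0
            )
            dprior = logpmf[kprop] - logpmf[kcur]
            delta = dloglik + dprior
            logu = np.log(rng.random(n))
            accept = ~bad & (logu < delta)
            if np.any(accept):
                k[accept, j] = kprop[accept]
                s = np.where(accept, snew, s)
                logs = np.where(accept & row_pos, log_snew, logs)
            acc["k"] += int(accept.sum())
            prop["k"] += n

        # --- chromosome-weight sweep
        if update_lambda:
            kf = k.astype(float)
            for j in range(m):
                lam_new = propose_lambda(lam, j, config.rate_lambda, rng)
                ratio = (1.0 - lam_new[j]) / (1.0 - lam[j])
                snew = ratio * (s - lam[j] * kf[:, j]) + lam_new[j] * kf[:, j]
                ok = ~row_pos | (snew > 0)
                loglam_new = np.log(lam_new)
                log_snew = np.log(np.where(snew > 0, snew, 1.0))
                delta = col_tot @ (loglam_new - loglam) - float(
                    np.where(row_pos, row_tot * (log_snew - logs), 0.0).sum()
                )
                prop["lambda"] += 1
                if np.all(ok) and np.log(rng.random()) < delta:
                    lam, loglam = lam_new, loglam_new
                    s = snew
                    logs = np.where(row_pos, log_snew, logs)
                    acc["lambda"] += 1
            if (it + 1) % 1000 == 0:
                # counteract float drift in the simplex constraint
                lam = lam / lam.sum()
                loglam = np.log(lam)

        # --- prior-sharpness update
        if update_p:
            step = rng.exponential(1.0 / config.rate_p)
            sign = 1.0 if rng.integers(0, 2) == 1 else -1.0
            cand = reflect(p + sign * step)
            logpmf_cand = log_k_prior_pmf(cand)
            hist = np.bincount(k.ravel(), minlength=N_STATES)
            occ = hist > 0
            prop["p"] += 1
            if np.any(np.isneginf(logpmf_cand[occ])):
                delta = -np.inf
            else:
                delta = float(hist[occ] @ (logpmf_cand[occ] - logpmf[occ]))
            if np.log(rng.random()) < delta:
                p = cand
                logpmf = logpmf_cand
                acc["p"] += 1

        # --- record
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            p_samples[rec] = p
            lambda_samples[rec] = lam
            active = n_counts > 0
            ll_terms = np.zeros_like(s, shape=(n, m))
            prod = lam[np.newaxis, :] * k
            ll_terms[active] = n_counts[active] * np.log(prod[active])
            loglik_samples[rec] = ll_terms.sum() - float(row_tot[row_pos] @ logs[row_pos])
            k_post[ii, jj, k] += 1
            if k_draws is not None:
                k_draws[rec] = k
            rec += 1

    rates = {name: (acc[name] / prop[name] if prop[name] else float("nan")) for name in acc}
    return ChainTrace(
        p_samples=p_samples,
        lambda_samples=lambda_samples,
        k_posterior_counts=k_post,
        loglik_samples=loglik_samples,
        k_samples=k_draws,
        acceptance_rates=rates,
        seed=seed,
        sample_ids=counts.sample_ids,
        chromosomes=counts.chromosomes,
        config=config,
    )


def run_chains(
    counts: CountMatrix, config: ChainConfig, progress=None
) -> list[ChainTrace]:
    """Run ``config.n_chains`` chains with seeds seed, seed+1, ..."""
    return [
        run_chain(counts, config, chain_index=c, progress=progress)
        for c in range(config.n_chains)
    ]


# ---------------------------------------------------------------------------
# Convergence diagnostics


def _psrf(chains: np.ndarray) -> float:
    """Potential scale reduction from a (chains x records) array.

    Defined as sqrt((W + B/N) / W) with W the mean within-chain
    variance and B the between-chain variance of the means scaled by
    N; identical chains give exactly 1.
    """
    c, n = chains.shape
    if n < 2:
        return float("nan")
    w = float(chains.var(axis=1, ddof=1).mean())
    b = float(n * chains.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    return float(np.sqrt((w + b / n) / w))


def _autocorr(x: np.ndarray, lag: int) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0 or lag >= len(x):
        return float("nan")
    return float(x[:-lag] @ x[lag:]) / denom


@dataclass
class ConvergenceReport:
    """Across-chain diagnostics for a multi-chain run."""

    table: pd.DataFrame  # parameter, psrf
    p_autocorrelation: dict[int, float]
    mode_agreement: float  # fraction of cells where all chains agree
    disagreeing_cells: list[tuple[str, str]]
    threshold: float = 1.1

    @property
    def converged(self) -> bool:
        finite = self.table["psrf"].dropna()
        return bool((finite <= self.threshold).all() and self.mode_agreement == 1.0)


def convergence_report(
    traces: Sequence[ChainTrace],
    lags: Sequence[int] = (1, 10, 100),
    threshold: float = 1.1,
) -> ConvergenceReport:
    """Between/within-chain scale reduction for p and each lambda_j,
    lag autocorrelation of p, and per-cell posterior-mode agreement.

    Raises
    ------
    ValidationError
        Fewer than two chains, or chains of unequal recorded length.
    """
    if len(traces) < 2:
        raise ValidationError("convergence assessment needs at least two chains")
    lengths = {t.n_recorded for t in traces}
    if len(lengths) != 1:
        raise ValidationError(f"chains have unequal recorded lengths: {sorted(lengths)}")

    rows = [{"parameter": "p", "psrf": _psrf(np.stack([t.p_samples for t in traces]))}]
    chroms = traces[0].chromosomes
    for j, name in enumerate(chroms):
        arr = np.stack([t.lambda_samples[:, j] for t in traces])
        rows.append({"parameter": f"lambda_{name}", "psrf": _psrf(arr)})
    table = pd.DataFrame(rows)

    p_ac = {
        lag: float(np.mean([_autocorr(t.p_samples, lag) for t in traces])) for lag in lags
    }

    modes = np.stack([t.k_posterior_counts.argmax(axis=2) for t in traces])
    agree = (modes == modes[0]).all(axis=0)
    sample_ids = traces[0].sample_ids
    bad_cells = [
        (sample_ids[i], chroms[j]) for i, j in zip(*np.nonzero(~agree))
    ]
    return ConvergenceReport(
        table=table,
        p_autocorrelation=p_ac,
        mode_agreement=float(agree.mean()),
        disagreeing_cells=bad_cells,
        threshold=threshold,
    )
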