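"""The probabilistic model for per-chromosome dosage.

Observed data are whole-chromosome read counts ``n_ij`` for sample i
and chromosome j.  Latent quantities:

* ``lambda`` — a simplex of m chromosome weights, the expected share
  of reads per chromosome at baseline dosage; interpretable as the
  effective mapping-target length of each chromosome.  Prior:
  Dirichlet(1, ..., 1) (uniform on the simplex).
* ``k_ij`` — the integer ploidy (copy number of the homologous set)
  of chromosome j in sample i, on {0, ..., 12} with hexaploid
  baseline 6.  Prior: a reflected, truncated geometric distribution
  centred at 6, P(k) ∝ (1 - p)^|k - 6|.
* ``p`` — the geometric decay (sharpness) of the ploidy prior, with a
  uniform[0, 1] hyperprior; p=0 is flat over 0..12, p→1 concentrates
  on 6.

Likelihood: reads of sample i fall on chromosomes multinomially with
cell probabilities lambda_j * k_ij / sum_v lambda_v * k_iv.  The
multinomial coefficient is a function of the data alone, so it is
omitted throughout; every Metropolis–Hastings ratio it would enter
cancels it.  All computation is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import CountMatrix
from .errors import DomainError, InvalidStateError, ValidationError

#: Hard ceiling of the ploidy state space (twice the hexaploid baseline).
PLOIDY_MAX: int = 12
#: Expected (baseline) ploidy.
BASELINE_PLOIDY: int = 6
#: Number of ploidy states, 0..12.
N_STATES: int = PLOIDY_MAX + 1


def k_prior_pmf(p: float) -> np.ndarray:
    """Reflected truncated geometric pmf over ploidy states 0..12.

    ``pmf[k] = (1-p)^|k-6| / sum_i (1-p)^|i-6|``.  Symmetric about 6;
    p=0 gives the uniform distribution, p=1 a point mass at 6 (with the
    convention 0^0 = 1).

    Raises
    ------
    DomainError
        If p is outside [0, 1].
    """
    if not 0.0 <= p <= 1.0 or not np.isfinite(p):
        raise DomainError(f"sharpness p must lie in [0, 1], got {p}")
    d = np.abs(np.arange(N_STATES) - BASELINE_PLOIDY)
    with np.errstate(invalid="ignore"):
        w = np.power(1.0 - p, d, dtype=float)
    if p == 1.0:
        w = np.where(d == 0, 1.0, 0.0)
    return w / w.sum()


def log_k_prior_pmf(p: float) -> np.ndarray:
    """log of :func:`k_prior_pmf`, with -inf where the pmf is 0."""
    pmf = k_prior_pmf(p)
    with np.errstate(divide="ignore"):
        return np.log(pmf)


def validate_ploidy(k: np.ndarray) -> np.ndarray:
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        raise ValidationError("ploidy matrix must be integer")
    if k.min(initial=0) < 0 or k.max(initial=0) > PLOIDY_MAX:
        raise ValidationError(f"ploidy entries must lie in 0..{PLOIDY_MAX}")
    return k


def validate_weights(lam: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 1:
        raise ValidationError("chromosome weights must be a vector")
    if np.any(lam <= 0.0) or np.any(lam >= 1.0):
        raise ValidationError("chromosome weights must lie strictly in (0, 1)")
    if abs(lam.sum() - 1.0) > atol:
        raise ValidationError(f"chromosome weights must sum to 1, got {lam.sum()!r}")
    return lam


def log_likelihood(counts: CountMatrix, lam: np.ndarray, k: np.ndarray) -> float:
    """Multinomial log-likelihood (coefficient omitted).

    ``sum_ij n_ij * log(lambda_j k_ij / sum_v lambda_v k_iv)``.

    Returns -inf when some cell has ``k_ij = 0`` with ``n_ij > 0``:
    reads cannot map to an absent chromosome, so the state has zero
    probability (but is a legal proposal — it is simply always
    rejected).

    Raises
    ------
    InvalidStateError
        If a sample with reads has *every* k entry zero: the cell
        probabilities are 0/0 there and the density is undefined, not
        zero.
    """
    lam = validate_weights(lam)
    k = validate_ploidy(k)
    n = counts.counts
    if k.shape != n.shape or lam.shape != (n.shape[1],):
        raise ValidationError("shape mismatch between counts, weights, ploidy")
    row_totals = counts.row_totals
    s = k @ lam  # per-sample normalizer sum_v lambda_v k_iv
    dead = (s <= 0.0) & (row_totals > 0)
    if np.any(dead):
        raise InvalidStateError(
            f"sample(s) {list(np.flatnonzero(dead))} have all-zero ploidy "
            "but positive read counts; the multinomial is undefined"
        )
    if np.any((k == 0) & (n > 0)):
        return float("-inf")
    active = n > 0
    prod = lam[np.newaxis, :] * k
    term = np.zeros_like(prod)
    term[active] = n[active] * np.log(prod[active])
    live = row_totals > 0
    return float(term.sum() - row_totals[live] @ np.log(s[live]))


def log_prior_k(k: np.ndarray, p: float) -> float:
    """Joint log prior of a ploidy matrix: sum of iid reflected-geometric
    terms.  -inf when p=1 and any entry differs from 6."""
    k = validate_ploidy(k)
    logpmf = log_k_prior_pmf(p)
    hist = np.bincount(k.ravel(), minlength=N_STATES)
    occupied = hist > 0
    if np.any(np.isneginf(logpmf[occupied])):
        return float("-inf")
    return float(hist[occupied] @ logpmf[occupied])


@dataclass
class ModelState:
    """Bundle of the current sampler state with cached log terms.

    Caches must equal from-scratch recomputation; :meth:`check_caches`
    asserts this within 1e-8 and is used in tests and defensive
    checkpoints.
    """

    lam: np.ndarray
    k: np.ndarray
    p: float
    cached_loglik: float
    cached_logprior_k: float

    @classmethod
    def fresh(cls, counts: CountMatrix, lam: np.ndarray, k: np.ndarray, p: float) -> "ModelState":
        return cls(
            lam=np.asarray(lam, dtype=float).copy(),
            k=np.asarray(k).copy(),
            p=float(p),
            cached_loglik=log_likelihood(counts, lam, k),
            cached_logprior_k=log_prior_k(k, p),
        )

    def check_caches(self, counts: CountMatrix, atol: float = 1e-8) -> None:
        ll = log_likelihood(counts, self.lam, self.k)
        lp = log_prior_k(self.k, self.p)
        for name, cached, fresh_v in (
            ("loglik", self.cached_loglik, ll),
            ("logprior_k", self.cached_logprior_k, lp),
        ):
            if cached == fresh_v:  # covers -inf == -inf
                continue
            if not np.isclose(cached, fresh_v, rtol=0.0, atol=atol):
                raise ValidationError(
                    f"stale cache {name}: cached {cached!r} != recomputed {fresh_v!r}"
                )

    def to_json_dict(self) -> dict:
        return {
            "lam": self.lam.tolist(),
            "k": self.k.tolist(),
            "p": self.p,
            "cached_loglik": self.cached_loglik,
            "cached_logprior_k": self.cached_logprior_k,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelState":
        return cls(
            lam=np.asarray(d["lam"], dtype=float),
            k=np.asarray(d["k"], dtype=np.int64),
            p=float(d["p"]),
            cached_loglik=float(d["cached_loglik"]),
            cached_logprior_k=float(d["cached_logprior_k"]),
        )
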