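"""Posterior summaries, aneuploidy calls, cohort tables and exact tests.

A cell (sample, chromosome) is called a *gain* when its posterior mode
is >= 7 with mode probability above the call threshold, a *loss* when
the mode is <= 5 above threshold, *euploid* when the mode is the
hexaploid baseline 6, and *uncertain* otherwise.  Cohort tables
aggregate calls into per-chromosome ploidy-5/ploidy-7 counts and
per-cohort gain/loss/percent summaries, and Fisher's exact test
compares cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .counts import COHORTS, SampleMetadata
from .errors import DomainError, ValidationError
from .mcmc import ChainTrace
from .model import BASELINE_PLOIDY, N_STATES

CALL_ORDER = ("loss", "euploid", "gain", "uncertain")


def _mode_with_tiebreak(pmf: np.ndarray) -> int:
    """Argmax of a 13-state pmf; ties resolve to 6 if tied, else to the
    state nearest 6 (then the smaller state)."""
    best = pmf.max()
    tied = np.flatnonzero(pmf == best)
    if len(tied) == 1:
        return int(tied[0])
    if BASELINE_PLOIDY in tied:
        return BASELINE_PLOIDY
    return int(min(tied, key=lambda s: (abs(s - BASELINE_PLOIDY), s)))


def summarize_posterior(
    traces: ChainTrace | Sequence[ChainTrace], min_prob: float = 0.95
) -> pd.DataFrame:
    """Per-cell posterior pmf over ploidy states, mode, and call.

    Accepts one trace or several (chains are pooled).  Returns a tidy
    frame with one row per (sample, chromosome): columns ``sample_id``,
    ``chromosome``, ``mode``, ``mode_prob``, ``call`` and ``pmf_0`` ..
    ``pmf_12``.
    """
    if isinstance(traces, ChainTrace):
        traces = [traces]
    if not traces:
        raise ValidationError("no traces given")
    counts = sum(t.k_posterior_counts for t in traces)
    total = counts.sum(axis=2)
    if np.any(total == 0):
        raise ValidationError("empty trace: no recorded draws")
    pmf = counts / total[:, :, np.newaxis]
    sample_ids = traces[0].sample_ids
    chroms = traces[0].chromosomes

    rows = []
    for i, sid in enumerate(sample_ids):
        for j, chrom in enumerate(chroms):
            cell = pmf[i, j]
            mode = _mode_with_tiebreak(cell)
            mode_prob = float(cell[mode])
            if mode == BASELINE_PLOIDY:
                call = "euploid"
            elif mode >= BASELINE_PLOIDY + 1 and mode_prob >= min_prob:
                call = "gain"
            elif mode <= BASELINE_PLOIDY - 1 and mode_prob >= min_prob:
                call = "loss"
            else:
                call = "uncertain"
            row = {
                "sample_id": sid,
                "chromosome": chrom,
                "mode": mode,
                "mode_prob": mode_prob,
                "call": call,
            }
            row.update({f"pmf_{s}": float(cell[s]) for s in range(N_STATES)})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortTable:
    """Aggregated aneuploidy calls.

    ``per_chromosome``: rows = chromosomes, a (ploidy5, ploidy7) count
    column pair per cohort.  ``summary``: rows = loss/gain/total
    aneuploids/no aneuploidy/total trees/percent aneuploids, one
    column per cohort.  ``notes`` records definitional caveats that a
    reader of the table should see.
    """

    per_chromosome: pd.DataFrame
    summary: pd.DataFrame
    notes: list[str]


def cohort_tables(
    calls: pd.DataFrame, metadata: Sequence[SampleMetadata]
) -> CohortTable:
    """Build per-chromosome and per-cohort aneuploidy count tables.

    A sample counts as aneuploid if it carries at least one gain or
    loss call.  Percent aneuploids = 100 * aneuploid samples / total
    samples in the cohort (the total-trees denominator; an alternative
    convention divides by the euploid count instead — see ``notes``).
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    unknown = sorted(set(calls["sample_id"]) - set(meta_by_id))
    if unknown:
        raise ValidationError(f"calls reference samples without metadata: {unknown}")
    bad_cohorts = sorted({m.cohort for m in metadata} - set(COHORTS))
    if bad_cohorts:
        raise ValidationError(f"unknown cohort labels: {bad_cohorts}")

    chroms = list(dict.fromkeys(calls["chromosome"]))
    cohorts = [c for c in COHORTS if any(m.cohort == c for m in metadata)]
    per_chrom = pd.DataFrame(
        0,
        index=pd.Index(chroms, name="chromosome"),
        columns=pd.MultiIndex.from_product([cohorts, ["ploidy5", "ploidy7"]]),
    )
    aneuploid_samples: dict[str, set[str]] = {c: set() for c in cohorts}
    loss_counts = {c: 0 for c in cohorts}
    gain_counts = {c: 0 for c in cohorts}
    for _, row in calls.iterrows():
        if row["call"] not in ("gain", "loss"):
            continue
        cohort = meta_by_id[row["sample_id"]].cohort
        side = "ploidy7" if row["call"] == "gain" else "ploidy5"
        per_chrom.loc[row["chromosome"], (cohort, side)] += 1
        aneuploid_samples[cohort].add(row["sample_id"])
        if row["call"] == "gain":
            gain_counts[cohort] += 1
        else:
            loss_counts[cohort] += 1

    totals = {c: sum(1 for m in metadata if m.cohort == c) for c in cohorts}
    summary = pd.DataFrame(
        {
            c: {
                "loss_of_chromosome": loss_counts[c],
                "gain_of_chromosome": gain_counts[c],
                "total_aneuploids": len(aneuploid_samples[c]),
                "no_aneuploidy": totals[c] - len(aneuploid_samples[c]),
                "total_trees": totals[c],
                "percent_aneuploids": (
                    100.0 * len(aneuploid_samples[c]) / totals[c] if totals[c] else 0.0
                ),
            }
            for c in cohorts
        }
    )
    notes = [
        "percent_aneuploids uses total trees as the denominator "
        "(aneuploids / total * 100); dividing by the euploid count "
        "instead gives a slightly larger figure for cohorts with "
        "aneuploids",
        "a sample with calls on several chromosomes counts once in "
        "total_aneuploids but contributes every call to the "
        "loss/gain rows",
    ]
    return CohortTable(per_chromosome=per_chrom, summary=summary, notes=notes)


def fisher_exact(
    table: Sequence[Sequence[int]] | np.ndarray,
    sided: Literal["two_sided_min_likelihood", "less", "greater"] = "two_sided_min_likelihood",
) -> float:
    """Fisher's exact test on a 2x2 contingency table.

    With margins fixed, the first cell ``a`` follows a hypergeometric
    distribution.  ``less``/``greater`` sum the corresponding tail of
    a; ``two_sided_min_likelihood`` sums the probability of every
    table (same margins) whose point probability does not exceed the
    observed table's — the convention of R's ``fisher.test`` and
    scipy's two-sided test.

    Returns the p-value, always in (0, 1].
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise DomainError("contingency table cells must be nonnegative")
    if t.sum() == 0:
        raise DomainError("all-zero contingency table")
    a = int(t[0, 0])
    r1 = int(t[0, 0] + t[0, 1])
    c1 = int(t[0, 0] + t[1, 0])
    n = int(t.sum())
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    if sided == "less":
        p = pmf[support <= a].sum()
    elif sided == "greater":
        p = pmf[support >= a].sum()
    elif sided == "two_sided_min_likelihood":
        # small relative slack absorbs float noise when comparing
        # mathematically equal point probabilities
        p = pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()
    else:
        raise DomainError(f"unknown sidedness {sided!r}")
    return float(min(p, 1.0))


def fisher_exact_exhaustive(
    table: Sequence[Sequence[int]] | np.ndarray,
    sided: Literal["two_sided_min_likelihood", "less", "greater"] = "two_sided_min_likelihood",
) -> Fraction:
    """Rational-arithmetic Fisher p-value by direct enumeration.

    Independent oracle for :func:`fisher_exact`: enumerates every table
    with the observed margins using exact binomial coefficients; no
    floating point.  Only suitable for small margins.
    """
    from math import comb

    t = np.asarray(table, dtype=np.int64)
    a = int(t[0, 0])
    r1 = int(t[0, 0] + t[0, 1])
    c1 = int(t[0, 0] + t[1, 0])
    n = int(t.sum())
    if n == 0:
        raise DomainError("all-zero contingency table")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    denom = comb(n, c1)
    probs = {x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    if sided == "less":
        return sum(v for x, v in probs.items() if x <= a)
    if sided == "greater":
        return sum(v for x, v in probs.items() if x >= a)
    return sum(v for v in probs.values() if v <= p_obs)
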