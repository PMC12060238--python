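"""Synthetic read-count generation from the model's own generative
process.

Each sample draws a total depth (log-normal by default), then
distributes reads over the 11 chromosomes multinomially with cell
probabilities proportional to lambda_j * k_ij, optionally distorted by
multiplicative per-(PCR-group, chromosome) batch factors.  Planted
whole-chromosome gains and losses on the hexaploid baseline give
ground truth for recovery tests.

What this emulates: per-sample depth variation, chromosome-share
structure, whole-chromosome dosage events, and batch-like
amplification bias.  What it does not: read-level error, GC or
mappability structure within chromosomes, partial (segmental) events,
or mosaicism — the model itself excludes those too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .counts import (
    DEFAULT_CHROMOSOMES,
    CountMatrix,
    SampleMetadata,
    write_idxstats,
    write_metadata_table,
)
from .errors import ValidationError
from .model import BASELINE_PLOIDY, PLOIDY_MAX


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters for one simulated cohort.

    ``chromosome_weights=None`` means uniform over the chromosomes.
    ``depth_per_sample`` may be an explicit vector of expected depths,
    or None to draw each sample's depth log-normally with
    ``depth_median`` and ``depth_sigma`` (median 2e5 reads, sigma 0.5:
    a realistic spread for a targeted-capture cohort).  ``pcr_groups``
    maps sample index -> group label; per-(group, chromosome)
    multiplicative factors are drawn uniformly in
    1 +/- ``batch_magnitude``.
    """

    n_samples: int
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    chromosome_weights: tuple[float, ...] | None = None
    baseline_ploidy: int = BASELINE_PLOIDY
    planted_events: tuple[tuple[int, int, int], ...] = ()  # (sample, chrom, k)
    depth_per_sample: tuple[float, ...] | None = None
    depth_median: float = 2e5
    depth_sigma: float = 0.5
    pcr_groups: Mapping[int, int] | None = None
    batch_magnitude: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.chromosomes)
        if self.n_samples < 1:
            raise ValidationError("need at least one sample")
        if self.chromosome_weights is not None:
            w = np.asarray(self.chromosome_weights, dtype=float)
            if w.shape != (m,) or np.any(w <= 0):
                raise ValidationError("chromosome_weights must be m positive values")
        if not 0 <= self.baseline_ploidy <= PLOIDY_MAX:
            raise ValidationError("baseline ploidy out of range")
        for i, j, k in self.planted_events:
            if not (0 <= i < self.n_samples and 0 <= j < m):
                raise ValidationError(f"planted event ({i},{j},{k}) outside the matrix")
            if not 0 <= k <= PLOIDY_MAX:
                raise ValidationError(f"planted ploidy {k} outside 0..{PLOIDY_MAX}")
        if self.depth_per_sample is not None:
            d = np.asarray(self.depth_per_sample, dtype=float)
            if d.shape != (self.n_samples,) or np.any(d <= 0):
                raise ValidationError("depth_per_sample must be n positive values")
        if self.depth_median <= 0 or self.depth_sigma < 0:
            raise ValidationError("depth distribution parameters must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a simulated count matrix."""

    k: np.ndarray  # true ploidy matrix
    lam: np.ndarray  # true chromosome weights
    depths: np.ndarray  # realized per-sample total counts
    group_factors: dict[int, np.ndarray] | None  # group -> per-chromosome factor

    def to_json_dict(self) -> dict:
        return {
            "k": self.k.tolist(),
            "lam": self.lam.tolist(),
            "depths": self.depths.tolist(),
            "group_factors": (
                {str(g): f.tolist() for g, f in self.group_factors.items()}
                if self.group_factors
                else None
            ),
        }


def expected_shares(spec: SimulationSpec) -> np.ndarray:
    """Expected per-cell read shares lambda_j k_ij / sum_v lambda_v k_iv
    (before batch factors)."""
    m = len(spec.chromosomes)
    lam = (
        np.full(m, 1.0 / m)
        if spec.chromosome_weights is None
        else np.asarray(spec.chromosome_weights, float) / np.sum(spec.chromosome_weights)
    )
    k = np.full((spec.n_samples, m), spec.baseline_ploidy, dtype=np.int64)
    for i, j, kk in spec.planted_events:
        k[i, j] = kk
    prod = lam[np.newaxis, :] * k
    denom = prod.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValidationError("a sample has all-zero expected shares")
    return prod / denom


def simulate_counts(spec: SimulationSpec) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix from the generative model.

    Deterministic for a fixed spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.chromosomes)
    lam = (
        np.full(m, 1.0 / m)
        if spec.chromosome_weights is None
        else np.asarray(spec.chromosome_weights, float) / np.sum(spec.chromosome_weights)
    )
    k = np.full((spec.n_samples, m), spec.baseline_ploidy, dtype=np.int64)
    for i, j, kk in spec.planted_events:
        k[i, j] = kk

    if spec.depth_per_sample is not None:
        depths = np.asarray(spec.depth_per_sample, dtype=float)
    else:
        depths = spec.depth_median * np.exp(
            rng.normal(0.0, spec.depth_sigma, size=spec.n_samples)
        )

    factors = None
    group_of = None
    if spec.pcr_groups is not None:
        group_of = {int(i): int(g) for i, g in spec.pcr_groups.items()}
        groups = sorted(set(group_of.values()))
        factors = {
            g: rng.uniform(1.0 - spec.batch_magnitude, 1.0 + spec.batch_magnitude, size=m)
            for g in groups
        }

    counts = np.zeros((spec.n_samples, m), dtype=np.int64)
    for i in range(spec.n_samples):
        prob = lam * k[i]
        if group_of is not None and i in group_of:
            prob = prob * factors[group_of[i]]
        total = prob.sum()
        if total == 0:
            raise ValidationError(f"sample {i} has all-zero cell probabilities")
        n_reads = int(np.round(depths[i]))
        if n_reads <= 0:
            raise ValidationError(f"sample {i} drew nonpositive depth {n_reads}")
        counts[i] = rng.multinomial(n_reads, prob / total)

    sample_ids = tuple(f"S{i:04d}" for i in range(spec.n_samples))
    cm = CountMatrix(counts, sample_ids, spec.chromosomes)
    truth = SyntheticTruth(
        k=k, lam=lam, depths=counts.sum(axis=1).astype(float), group_factors=factors
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Study-scale fixture


#: (cohort, chromosome label, call) planted events echoing the field
#: study design: per-chromosome gain/loss placement for the wild
#: second-growth cohort and the vegetatively propagated cohort; the
#: old-growth cohort carries none.
_SECOND_GROWTH_EVENTS = [
    ("chr1", 7), ("chr3", 7), ("chr6", 7), ("chr7", 7),
    ("chr8", 7), ("chr9", 7), ("chr10", 7), ("chr10", 7),
    ("chr4", 5),
]
_VEGETATIVE_EVENTS = [
    ("chr1", 5), ("chr1", 5), ("chr3", 5), ("chr6", 5), ("chr7", 5),
    ("chr9", 5), ("chr10", 5), ("chr11", 5), ("chr11", 5),
    ("chr8", 7), ("chr9", 7),
]
_COHORT_SIZES = {"old_growth": 56, "second_growth": 218, "vegetative": 82}


def make_paper_scale_fixture(
    seed: int = 0,
    depth_median: float = 2e5,
    n_pcr_groups: int = 5,
) -> tuple[CountMatrix, list[SampleMetadata], SyntheticTruth]:
    """Simulate a full study-scale cohort: 56 old-growth + 218
    second-growth + 82 vegetatively propagated samples over 11
    chromosomes, with 20 planted whole-chromosome events (9 in second
    growth: 8 gains + 1 loss; 11 in the vegetative cohort: 2 gains +
    9 losses; none in old growth), each in a distinct sample, and five
    PCR-cycle groups with mild multiplicative batch factors.
    """
    rng = np.random.default_rng(seed)
    chroms = DEFAULT_CHROMOSOMES
    cohort_of: list[str] = []
    for cohort in ("old_growth", "second_growth", "vegetative"):
        cohort_of.extend([cohort] * _COHORT_SIZES[cohort])
    n = len(cohort_of)

    events: list[tuple[int, int, int]] = []
    offset_second = _COHORT_SIZES["old_growth"]
    offset_veg = offset_second + _COHORT_SIZES["second_growth"]
    # one event per sample; carrier samples chosen at random within cohort
    carriers_sg = rng.choice(
        _COHORT_SIZES["second_growth"], size=len(_SECOND_GROWTH_EVENTS), replace=False
    )
    for (chrom, k), rel in zip(_SECOND_GROWTH_EVENTS, carriers_sg):
        events.append((offset_second + int(rel), chroms.index(chrom), k))
    carriers_vg = rng.choice(
        _COHORT_SIZES["vegetative"], size=len(_VEGETATIVE_EVENTS), replace=False
    )
    for (chrom, k), rel in zip(_VEGETATIVE_EVENTS, carriers_vg):
        events.append((offset_veg + int(rel), chroms.index(chrom), k))

    groups = {i: int(rng.integers(1, n_pcr_groups + 1)) for i in range(n)}
    spec = SimulationSpec(
        n_samples=n,
        chromosomes=chroms,
        planted_events=tuple(events),
        depth_median=depth_median,
        pcr_groups=groups,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cm, truth = simulate_counts(spec)
    metadata = [
        SampleMetadata(cm.sample_ids[i], cohort_of[i], groups[i]) for i in range(n)
    ]
    return cm, metadata, truth


def write_fixture(
    outdir: str | Path,
    counts: CountMatrix,
    metadata: Sequence[SampleMetadata],
    truth: SyntheticTruth,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write one idxstats file per sample, a metadata TSV, and the
    ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = chromosome_lengths or {c: 0 for c in counts.chromosomes}
    for i, sid in enumerate(counts.sample_ids):
        rows = list(zip(counts.chromosomes, (int(x) for x in counts.counts[i])))
        write_idxstats(rows, lengths, outdir / f"{sid}.idxstats.tsv")
    write_metadata_table(list(metadata), outdir / "metadata.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
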