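"""Read-count ingestion: samtools-idxstats files, plain count tables,
and sample metadata.

The model consumes whole-chromosome mapped-read counts, one row per
sample.  Counts are expected to come from an upstream alignment
pipeline (deduplicated, high-mapping-quality reads); this module only
parses and validates, it performs no filtering of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Canonical chromosome labels of the giant sequoia (Sequoiadendron
#: giganteum) karyotype used as the mapping reference: 11 chromosomes.
DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 12))

#: Closed set of cohort labels.
COHORTS: tuple[str, ...] = ("old_growth", "second_growth", "vegetative")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study annotation.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    cohort : str
        One of ``old_growth``, ``second_growth``, ``vegetative``
        (wild >300-year stands, 40–100-year managed stands, and
        vegetatively propagated greenhouse material respectively).
    pcr_cycle_group : int or None
        PCR-amplification-cycle stratum label (1–5), or None if
        unknown.
    """

    sample_id: str
    cohort: str
    pcr_cycle_group: int | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"unknown cohort {self.cohort!r} for sample {self.sample_id!r}; "
                f"expected one of {COHORTS}"
            )


@dataclass(frozen=True)
class CountMatrix:
    """Mapped-read counts, samples x chromosomes.

    ``counts[i, j]`` is the number of reads from sample ``i`` mapping to
    chromosome ``j``.  ``N`` is the grand total.  Rows with zero total
    are permitted at this level (they arise in data-free prior-recovery
    runs); :func:`build_count_matrix` rejects them for real data.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if c.shape != (len(self.sample_ids), len(self.chromosomes)):
            raise ValidationError(
                f"counts shape {c.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.chromosomes)} chromosomes"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValidationError("counts must be integers")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValidationError("counts must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValidationError("chromosome names must be unique")
        object.__setattr__(self, "counts", np.ascontiguousarray(c, dtype=np.int64))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.counts.shape[1]

    @property
    def N(self) -> int:
        """Total read count across all samples and chromosomes."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.chromosomes)
        ).rename_axis("sample_id")

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Row subset in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in sample_ids]
        return CountMatrix(self.counts[rows], tuple(sample_ids), self.chromosomes)


def read_idxstats(
    stream: IO[str] | Iterable[str],
    keep: Mapping[str, str],
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> list[tuple[str, int]]:
    """Parse one samtools-idxstats output and extract mapped counts.

    idxstats emits one row per reference sequence with four
    tab-separated fields: sequence name, sequence length, number of
    mapped read segments, number of unmapped read segments (plus a
    final ``*`` row for fully unmapped reads).

    Parameters
    ----------
    stream
        Text lines of one idxstats file.
    keep
        Map from raw sequence names to canonical chromosome labels.
        Sequences absent from the map (unplaced scaffolds, the ``*``
        row) are dropped.
    chromosomes
        Canonical chromosome labels that must all be present.

    Returns
    -------
    list of (chromosome, mapped_reads) in canonical order.

    Raises
    ------
    ParseError
        On a malformed row (wrong field count, non-integer count).
    SchemaError
        If a canonical chromosome has no row.
    """
    found: dict[str, int] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}: {line!r}"
            )
        name, length_s, mapped_s, unmapped_s = fields
        try:
            length = int(length_s)
            mapped = int(mapped_s)
            unmapped = int(unmapped_s)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer count field: {line!r}") from exc
        if length < 0 or mapped < 0 or unmapped < 0:
            raise ParseError(f"line {lineno}: negative count: {line!r}")
        if name not in keep:
            continue
        canonical = keep[name]
        if canonical in found:
            raise ParseError(
                f"line {lineno}: duplicate row for canonical chromosome {canonical!r}"
            )
        found[canonical] = mapped
    missing = [c for c in chromosomes if c not in found]
    if missing:
        raise SchemaError(f"canonical chromosomes missing from idxstats input: {missing}")
    return [(c, found[c]) for c in chromosomes]


def build_count_matrix(
    per_sample_counts: Mapping[str, Sequence[int]],
    metadata: Sequence[SampleMetadata],
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> CountMatrix:
    """Assemble a validated :class:`CountMatrix` from per-sample counts.

    Rows are ordered by the metadata sequence; every sample must carry
    metadata and a full-length count vector.  Samples with zero total
    depth are rejected (such samples carry no dosage information and
    are excluded from analysis upstream).
    """
    meta_ids = [m.sample_id for m in metadata]
    if len(set(meta_ids)) != len(meta_ids):
        raise ValidationError("duplicate sample_id in metadata")
    missing_meta = sorted(set(per_sample_counts) - set(meta_ids))
    if missing_meta:
        raise ValidationError(f"metadata missing for samples: {missing_meta}")
    missing_counts = [s for s in meta_ids if s not in per_sample_counts]
    if missing_counts:
        raise ValidationError(f"counts missing for samples: {missing_counts}")

    m = len(chromosomes)
    rows = []
    for sid in meta_ids:
        vec = np.asarray(per_sample_counts[sid], dtype=np.int64)
        if vec.shape != (m,):
            raise ValidationError(
                f"sample {sid!r}: expected {m} chromosome counts, got {vec.shape}"
            )
        if vec.sum() == 0:
            raise ValidationError(
                f"sample {sid!r} has zero total read count; "
                "insufficient sequencing depth, exclude it before assembly"
            )
        rows.append(vec)
    return CountMatrix(np.stack(rows), tuple(meta_ids), tuple(chromosomes))


# ---------------------------------------------------------------------------
# Plain-table dialect: TSV, header row of chromosome names, first column
# sample_id.  Chosen for hand-editability.

def write_count_table(counts: CountMatrix, path_or_buf) -> None:
    counts.to_frame().to_csv(path_or_buf, sep="\t")


def read_count_table(path_or_buf) -> CountMatrix:
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"count table contains non-integer entries: {exc}") from exc
    return CountMatrix(values, tuple(str(s) for s in df.index), tuple(df.columns))


def write_metadata_table(metadata: Sequence[SampleMetadata], path_or_buf) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "cohort": [m.cohort for m in metadata],
            "pcr_cycle_group": [m.pcr_cycle_group for m in metadata],
        }
    ).to_csv(path_or_buf, sep="\t", index=False)


def read_metadata_table(path_or_buf) -> list[SampleMetadata]:
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"sample_id", "cohort"}
    if not required.issubset(df.columns):
        raise SchemaError(f"metadata table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        group = row.get("pcr_cycle_group")
        if group is None or (isinstance(group, float) and np.isnan(group)):
            group = None
        else:
            group = int(group)
        out.append(SampleMetadata(str(row["sample_id"]), str(row["cohort"]), group))
    return out


def write_idxstats(
    counts: Sequence[tuple[str, int]],
    lengths: Mapping[str, int],
    path_or_buf,
    unmapped: int = 0,
) -> None:
    """Write counts in the 4-column idxstats dialect (with a ``*`` row)."""
    own = isinstance(path_or_buf, (str,)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        for chrom, mapped in counts:
            fh.write(f"{chrom}\t{lengths.get(chrom, 0)}\t{mapped}\t0\n")
        fh.write(f"*\t0\t0\t{unmapped}\n")
    finally:
        if own:
            fh.close()
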