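"""Hit-multiplicity analysis of BLAST tabular output.

In a hexaploid assembly, a single-copy coding sequence should align to
exactly six places; the distribution of hits-per-query over all query
sequences therefore peaks at the assembly's ploidy.  This module
parses 13-column tabular BLAST output (outfmt 6 extended with the
number of identical matches), counts hits per query, tabulates the
frequency-of-frequencies distribution, and splits 12-hit sets into
two identity-ranked groups of six (the signature of an older
whole-genome duplication layered on the hexaploidy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

#: Column names of the expected 13-field tabular output: the 12
#: standard outfmt-6 fields plus the number of identical matches.
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "nident",
)

_INT_COLUMNS = ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send", "nident")


@dataclass(frozen=True)
class BlastHit:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    nident: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ParseError(f"pident {self.pident} outside [0, 100]")
        if min(self.qstart, self.qend, self.sstart, self.send) < 1:
            raise ParseError("alignment coordinates must be positive")


def read_blast_table(path_or_buf) -> pd.DataFrame:
    """Read a 13-column tab-separated BLAST hit table."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST_COLUMNS):
        raise ParseError(
            f"expected {len(BLAST_COLUMNS)} tab-separated columns, got {df.shape[1]}"
        )
    df.columns = list(BLAST_COLUMNS)
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(np.int64)
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ParseError("pident outside [0, 100]")
    return df


def hits_per_query(hits: pd.DataFrame | Iterable[BlastHit]) -> pd.Series:
    """Number of hit rows per distinct query, duplicates included."""
    if isinstance(hits, pd.DataFrame):
        qseqids = hits["qseqid"]
    else:
        qseqids = pd.Series([h.qseqid for h in hits], dtype=object)
    if len(qseqids) == 0:
        return pd.Series(dtype=np.int64, name="hits")
    out = qseqids.value_counts(sort=False).astype(np.int64)
    out.name = "hits"
    out.index.name = "qseqid"
    return out


def frequency_of_frequencies(counts: pd.Series | dict) -> pd.DataFrame:
    """Tabulate how many queries share each hit count.

    Returns a frame with columns ``hits_per_query`` and ``n_queries``,
    sorted by hit count, histogram-ready.  Conserves the query count:
    ``n_queries`` sums to the number of distinct queries.
    """
    if isinstance(counts, dict):
        counts = pd.Series(counts, dtype=np.int64)
    if len(counts) == 0:
        return pd.DataFrame(columns=["hits_per_query", "n_queries"]).astype(np.int64)
    freq = counts.value_counts().sort_index()
    return pd.DataFrame(
        {"hits_per_query": freq.index.astype(np.int64), "n_queries": freq.values}
    ).reset_index(drop=True)


def deduplicate_queries(hits: pd.DataFrame) -> pd.DataFrame:
    """Drop queries whose full hit set duplicates another query's.

    Two queries are duplicates when their sets of
    (sseqid, sstart, send) triples are identical — they align to
    exactly the same places, as tandem-duplicated or identical CDS
    entries do.  The first query (in input order) of each duplicate
    class is kept.  This is a heuristic definition of "duplicate";
    callers needing a different rule can filter upstream.
    """
    signatures: dict[frozenset, str] = {}
    keep: list[str] = []
    for q, grp in hits.groupby("qseqid", sort=False):
        sig = frozenset(zip(grp["sseqid"], grp["sstart"], grp["send"]))
        if sig not in signatures:
            signatures[sig] = q
            keep.append(q)
    return hits[hits["qseqid"].isin(keep)].reset_index(drop=True)


@dataclass(frozen=True)
class TwelveSetSplit:
    """Identity-ranked split of a 12-hit set into two sixes."""

    high_group: pd.DataFrame
    low_group: pd.DataFrame
    mean_pident_high: float
    mean_pident_low: float
    ambiguous: bool  # True when the rank-6 boundary has tied pident


def split_twelve_set(hits: pd.DataFrame | Sequence[BlastHit]) -> TwelveSetSplit:
    """Split the 12 hits of one query into top-6 and bottom-6 by
    percent identity and report each group's mean pident.

    A clean split (the hexaploid six plus an older-duplication six)
    shows a clearly higher mean identity in the top group.  If the
    sixth and seventh ranked identities tie, the partition is
    arbitrary at the boundary and the result is flagged ``ambiguous``.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame([h.__dict__ for h in hits])
    if len(hits) != 12:
        raise DomainError(f"expected exactly 12 hits for one query, got {len(hits)}")
    ranked = hits.sort_values("pident", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    high = ranked.iloc[:6]
    low = ranked.iloc[6:]
    ambiguous = bool(ranked.loc[5, "pident"] == ranked.loc[6, "pident"])
    return TwelveSetSplit(
        high_group=high,
        low_group=low,
        mean_pident_high=float(high["pident"].mean()),
        mean_pident_low=float(low["pident"].mean()),
        ambiguous=ambiguous,
    )
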