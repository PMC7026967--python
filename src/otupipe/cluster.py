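"""Greedy de novo OTU clustering at a genetic-distance cutoff.

Reads are dereplicated into unique sequences, sorted by decreasing
total abundance (ties broken by lexicographic sequence order), and
processed in that order: each unique sequence joins the first existing
centroid whose genetic distance (see :mod:`otupipe.align`) is at or
below the cutoff, otherwise it founds a new OTU with itself as the
centroid.  The canonicalisation makes the result invariant to input
file order.

Two provably exactness-preserving shortcuts keep desk-scale runs fast
(see docs/methods.md for the inequalities):

* equal-length sequences with a small Hamming distance h are joined
  without the DP whenever the ungapped alignment is guaranteed to be
  within the cutoff (h <= max(2, 0.74 * cutoff * L));
* a shared-k-mer lower bound proves many centroid pairs are beyond the
  cutoff without aligning them (a pair within distance d over columns N
  differs in at most d*N columns, and each differing column can destroy
  at most k of the query's k-mers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from otupipe.align import Scoring, hamming, pairwise_distance

__all__ = ["OtuRecord", "CountTable", "greedy_cluster", "build_count_table"]

_KMER = 8
_ENC = {c: i for i, c in enumerate("ACGT")}


@dataclass
class OtuRecord:
    """One OTU: representative (centroid) sequence, per-sample counts,
    screening flags and (once assigned) a taxonomy call.  ``members``
    holds the ids of the clustered reads when the inputs carried ids.
    """

    otu_id: str
    representative: str
    counts: dict[str, int]
    flags: set[str] = field(default_factory=set)
    taxonomy: object | None = None
    members: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class CountTable:
    """Samples x OTUs integer count matrix with group metadata.

    The in-memory form of a mothur ``shared`` file: one row per sample,
    one column per OTU, plus a sample -> group mapping.
    """

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str], label: str = "0.05"):
        counts = counts.astype(np.int64)
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        groups = pd.Series(dict(groups), name="group")
        missing = [s for s in counts.index if s not in groups.index]
        if missing:
            raise KeyError(f"samples without group metadata: {missing}")
        self.counts = counts
        self.groups = groups.reindex(counts.index)
        self.label = label

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self, percent: bool = True) -> pd.DataFrame:
        """Per-sample composition; rows sum to 100 (percent) or 1."""
        scale = 100.0 if percent else 1.0
        sums = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(sums, axis=0) * scale

    def drop_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        keep = [c for c in self.counts.columns if c not in set(otu_ids)]
        return CountTable(self.counts[keep], self.groups, self.label)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.counts.equals(other.counts)
            and self.groups.equals(other.groups)
        )

    def __repr__(self) -> str:
        return f"CountTable({len(self.samples)} samples x {len(self.otu_ids)} OTUs)"


def _kmer_set(seq: str, k: int = _KMER) -> frozenset[int]:
    enc = [_ENC.get(c, 0) for c in seq]
    out = set()
    code = 0
    mask = (1 << (2 * k)) - 1
    for i, e in enumerate(enc):
        code = ((code << 2) | e) & mask
        if i >= k - 1:
            out.add(code)
    return frozenset(out)


def _dereplicate(
    reads_by_sample: Mapping[str, Sequence], samples: Sequence[str]
) -> list[tuple[str, dict[str, int], int, list[str]]]:
    """Collapse identical sequences; returns [(seq, per-sample counts,
    total, read ids)] sorted by decreasing total then lexicographic
    sequence."""
    table: dict[str, dict[str, int]] = {}
    ids: dict[str, list[str]] = {}
    for sample in samples:
        for read in reads_by_sample[sample]:
            if isinstance(read, str):
                seq = read.upper()
            else:
                seq = read.bases.upper()
                ids.setdefault(seq, []).append(read.id)
            per = table.setdefault(seq, {})
            per[sample] = per.get(sample, 0) + 1
    uniques = [(seq, per, sum(per.values()), ids.get(seq, [])) for seq, per in table.items()]
    uniques.sort(key=lambda t: (-t[2], t[0]))
    return uniques


def greedy_cluster(
    reads_by_sample: Mapping[str, Sequence],
    cutoff: float = 0.05,
    scoring: Scoring = Scoring(),
    id_prefix: str = "Ssd",
) -> list[OtuRecord]:
    """Cluster reads (strings or :class:`~otupipe.qc.Read`) per sample
    into OTUs at the given genetic-distance cutoff (default 5%, the
    recommended value for the V1-V3 region).

    Returns OTUs ordered by decreasing total abundance with zero-padded
    ids (``Ssd-00001`` ...).
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    samples = list(reads_by_sample)
    uniques = _dereplicate(reads_by_sample, samples)
    if not uniques:
        raise ValueError("no reads to cluster")

    cent_seqs: list[str] = []
    cent_counts: list[dict[str, int]] = []
    cent_kmers: list[frozenset[int]] = []
    cent_members: list[list[str]] = []

    for seq, per, _total, read_ids in uniques:
        L = len(seq)
        max_diff = math.ceil(cutoff * L / (1.0 - cutoff))
        q_kmers = None
        joined = None
        for ci, cseq in enumerate(cent_seqs):
            if len(cseq) == L:
                h = hamming(seq, cseq)
                if h <= 2:
                    # ungapped alignment provably canonical-optimal:
                    # distance is exactly h/L either way
                    if h <= cutoff * L:
                        joined = ci
                        break
                    continue
                if h <= 0.74 * cutoff * L:
                    # canonical distance <= (4/3) h/L <= cutoff
                    joined = ci
                    break
            if q_kmers is None:
                q_kmers = _kmer_set(seq)
            bound = len(q_kmers) - max_diff * _KMER
            if bound > 0 and len(q_kmers & cent_kmers[ci]) < bound:
                continue  # provably beyond the cutoff
            if pairwise_distance(seq, cseq, scoring) <= cutoff:
                joined = ci
                break
        if joined is None:
            cent_seqs.append(seq)
            cent_counts.append(dict(per))
            cent_kmers.append(q_kmers if q_kmers is not None else _kmer_set(seq))
            cent_members.append(list(read_ids))
        else:
            acc = cent_counts[joined]
            for s, c in per.items():
                acc[s] = acc.get(s, 0) + c
            cent_members[joined].extend(read_ids)

    order = sorted(
        range(len(cent_seqs)),
        key=lambda i: (-sum(cent_counts[i].values()), cent_seqs[i]),
    )
    return [
        OtuRecord(
            otu_id=f"{id_prefix}-{rank + 1:05d}",
            representative=cent_seqs[i],
            counts=cent_counts[i],
            members=cent_members[i],
        )
        for rank, i in enumerate(order)
    ]


def build_count_table(
    otus: Sequence[OtuRecord],
    sample_metadata: Mapping[str, str],
    label: str = "0.05",
    exclude_flagged: bool = True,
) -> CountTable:
    """Assemble the samples x OTUs matrix (columns in decreasing total
    abundance).  OTUs carrying screening flags are excluded when
    ``exclude_flagged``; samples present only in the metadata keep a
    row of zeros."""
    samples = list(sample_metadata)
    kept = [o for o in otus if not (exclude_flagged and o.flags)]
    kept.sort(key=lambda o: (-o.total, o.otu_id))
    data = {}
    for otu in kept:
        unknown = [s for s in otu.counts if s not in sample_metadata]
        if unknown:
            raise KeyError(f"OTU {otu.otu_id} counts reference unknown samples: {unknown}")
        data[otu.otu_id] = [otu.counts.get(s, 0) for s in samples]
    counts = pd.DataFrame(data, index=samples, dtype=np.int64)
    return CountTable(counts, dict(sample_metadata), label)
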