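"""Read-level quality screening for V1-V3 amplicon contigs.

A read is kept when (checked in this order, first failure reported):

1. the forward primer (27F) matches exactly at the 5' end and the
   reverse complement of the reverse primer (519R) exactly at the 3'
   end ("intact" primers = zero mismatches by default, configurable);
2. its full (untrimmed) length lies in [min_len, max_len], default
   400-580 nt;
3. at most ``max_low_qual_fraction`` (default 1%) of its bases have a
   Phred score below ``phred_floor`` (default 15).

Passing reads are returned with both primer regions trimmed off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "Read",
    "QcParams",
    "QcDecision",
    "reverse_complement",
    "screen_read",
    "screen_reads",
    "qc_summary",
]

#: 27F / 519R primer pair bracketing the 16S V1-V3 region (the
#: unambiguous variants used throughout the simulator and defaults).
FORWARD_PRIMER = "AGAGTTTGATCCTGGCTCAG"
REVERSE_PRIMER = "GTATTACCGCGGCTGCTG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """One quality-scored amplicon sequence."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QcParams:
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    min_len: int = 400
    max_len: int = 580
    phred_floor: int = 15
    max_low_qual_fraction: float = 0.01
    primer_mismatches: int = 0  # allowed mismatches per primer site

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if not (0.0 <= self.max_low_qual_fraction <= 1.0):
            raise ValueError("max_low_qual_fraction must be in [0, 1]")
        if self.primer_mismatches < 0:
            raise ValueError("primer_mismatches must be >= 0")


@dataclass(frozen=True)
class QcDecision:
    passed: bool
    reason: str  # ok | missing_forward_primer | missing_reverse_primer | too_short | too_long | low_quality
    trimmed_read: Read | None = None

    def __post_init__(self):
        if self.passed != (self.reason == "ok"):
            raise ValueError("reason must be 'ok' iff passed")


def _site_matches(site: str, primer: str, max_mismatch: int) -> bool:
    if len(site) != len(primer):
        return False
    if max_mismatch == 0:
        return site == primer
    return sum(a != b for a, b in zip(site, primer)) <= max_mismatch


def screen_read(read: Read, params: QcParams = QcParams()) -> QcDecision:
    """Apply the primer / length / quality criteria to one read.

    The length window is evaluated on the untrimmed read; on a pass the
    returned read has both primer regions removed.
    """
    n = len(read)
    fwd = params.forward_primer.upper()
    rev_rc = reverse_complement(params.reverse_primer.upper())
    if n == 0:
        return QcDecision(False, "too_short")
    if n < len(fwd) or not _site_matches(read.bases[: len(fwd)].upper(), fwd, params.primer_mismatches):
        return QcDecision(False, "missing_forward_primer")
    if n < len(fwd) + len(rev_rc) or not _site_matches(
        read.bases[n - len(rev_rc):].upper(), rev_rc, params.primer_mismatches
    ):
        return QcDecision(False, "missing_reverse_primer")
    if n < params.min_len:
        return QcDecision(False, "too_short")
    if n > params.max_len:
        return QcDecision(False, "too_long")
    low = sum(1 for q in read.quals if q < params.phred_floor)
    if low > params.max_low_qual_fraction * n:
        return QcDecision(False, "low_quality")
    trimmed = Read(
        read.id,
        read.bases[len(fwd): n - len(rev_rc)],
        read.quals[len(fwd): n - len(rev_rc)],
    )
    return QcDecision(True, "ok", trimmed)


def screen_reads(
    reads: Iterable[Read], params: QcParams = QcParams()
) -> tuple[list[Read], list[tuple[str, str]]]:
    """Screen a batch; returns (trimmed passing reads, [(id, reason)] rejections)."""
    passed: list[Read] = []
    rejected: list[tuple[str, str]] = []
    for read in reads:
        d = screen_read(read, params)
        if d.passed:
            passed.append(d.trimmed_read)
        else:
            rejected.append((read.id, d.reason))
    return passed, rejected


def qc_summary(
    reads_per_sample: Mapping[str, Sequence[Read]], params: QcParams = QcParams()
) -> pd.DataFrame:
    """Per-sample QC table: n_raw, n_passed and the mean Phred score
    over all bases of the passing reads (NaN when nothing passes)."""
    rows = []
    for sample, reads in reads_per_sample.items():
        passed, _ = screen_reads(reads, params)
        if passed:
            total = sum(sum(r.quals) for r in passed)
            nbases = sum(len(r) for r in passed)
            mean_phred = total / nbases
        else:
            mean_phred = np.nan
        rows.append((sample, len(list(reads)), len(passed), mean_phred))
    return pd.DataFrame(rows, columns=["sample", "n_raw", "n_passed", "mean_phred"]).set_index(
        "sample"
    )
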