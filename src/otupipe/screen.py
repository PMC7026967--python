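"""OTU-level artifact screens.

Three screens are applied to OTU representatives, in order:

1. **Bimera detection** — a simplified two-parent test: for every
   pair of sufficiently abundant candidate parents (total count at
   least twice the query's) and every breakpoint along the query, the
   identity of the left segment to parent A and of the right segment
   to parent B is computed from global alignments.  Identity is taken
   over the pair's *informative* columns — query positions matching at
   least one of the two parents; positions matching neither are almost
   always the query's own sequencing errors and carry no information
   about parentage, so they are excluded (as uchime's vote-based
   scoring does).  The query is flagged when the best two-parent
   split explains it (near-)perfectly — overall split identity at or
   above the threshold (default 99%) with both segments above a floor
   (default 95%) — while no single candidate parent explains the full
   length on its own (best full-length identity <= 95%).  The overall
   split identity, pooled over both segments' informative columns, is
   used rather than a per-segment 99% rule because each segment alone
   has too few informative columns for a 1% tolerance to absorb even
   one sequencing error that happens to match the wrong parent.
2. **End integrity** — against the closest reference of equal or
   longer length, more than ``max_end_gap`` (default 5) nucleotides
   missing from the 5' or 3' end of the alignment discards the OTU.
3. **Singleton screen** — OTUs with a single read are kept only with a
   perfect or near-perfect reference match: the alignment must span
   the whole OTU sequence with at most 1% dissimilar nucleotides.

Reference search is an exhaustive local alignment against a supplied
annotated FASTA (no external database or network dependence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from otupipe.align import Scoring, align_global, align_local, encode_dna
from otupipe.cluster import OtuRecord

__all__ = [
    "ReferenceRecord",
    "ReferenceHit",
    "BimeraCall",
    "search_reference",
    "detect_bimera",
    "end_integrity_screen",
    "singleton_screen",
    "apply_screens",
]


@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated reference sequence (``>id lineage`` in FASTA)."""

    id: str
    seq: str
    lineage: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReferenceHit:
    """Best reference match; spans are 1-based inclusive (BLAST style)."""

    query_id: str
    subject_id: str
    identity_fraction: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_length: int
    subject_length: int


@dataclass(frozen=True)
class BimeraCall:
    flagged: bool
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None
    split_identity: float = 0.0
    best_single_identity: float = 0.0


def search_reference(
    query_id: str,
    query: str,
    reference: Sequence[ReferenceRecord],
    scoring: Scoring = Scoring(),
) -> ReferenceHit | None:
    """Best local alignment among references of equal or longer
    sequence length, ranked by alignment score (identity alone would
    let a short spurious near-perfect block on the wrong reference
    outrank a full-length match).  Ties broken by longer subject, then
    lexicographic id.  Returns None when no reference is eligible."""
    if not reference:
        raise ValueError("empty reference set")
    best_score: float | None = None
    best_hit: ReferenceHit | None = None
    for rec in sorted(reference, key=lambda r: (-len(r.seq), r.id)):
        if len(rec.seq) < len(query):
            continue
        hit = align_local(query, rec.seq, scoring)
        if best_score is None or hit.score > best_score:
            best_score = hit.score
            best_hit = ReferenceHit(
                query_id=query_id,
                subject_id=rec.id,
                identity_fraction=hit.identity,
                q_start=hit.q_start,
                q_end=hit.q_end,
                s_start=hit.s_start,
                s_end=hit.s_end,
                query_length=len(query),
                subject_length=len(rec.seq),
            )
    return best_hit


def _match_profile(query: str, parent: str, scoring: Scoring) -> np.ndarray:
    """Boolean per-query-position vector: True where the position is
    aligned as a match in the global alignment against the parent."""
    aln = align_global(query, parent, scoring)
    out = np.zeros(len(query), dtype=bool)
    qpos = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            out[qpos] = ca == cb
            qpos += 1
    return out


def detect_bimera(
    otu: OtuRecord,
    candidate_parents: Sequence[OtuRecord],
    split_identity: float = 0.99,
    max_single_identity: float = 0.95,
    abundance_skew: float = 2.0,
    segment_floor: float = 0.95,
    min_segment_columns: int = 20,
    scoring: Scoring = Scoring(),
) -> BimeraCall:
    """Two-parent chimera test on an OTU representative.

    ``candidate_parents`` are filtered to the uchime-style skew rule
    (parent total >= abundance_skew x query total); with no candidates
    the OTU is not flagged.  A query whose best single-parent
    full-length identity exceeds ``max_single_identity`` is a variant,
    never a bimera (global veto).  Otherwise every parent pair is
    scanned for the breakpoint maximising the overall split identity
    over the pair's informative columns (positions matching at least
    one parent; positions matching neither are the query's own
    sequencing errors and are excluded); the query is flagged when the
    best split reaches ``split_identity`` overall with both segments
    at or above ``segment_floor`` and at least ``min_segment_columns``
    informative columns on each side of the breakpoint.
    """
    query = otu.representative
    L = len(query)
    parents = [
        p
        for p in candidate_parents
        if p.total >= abundance_skew * otu.total and p.otu_id != otu.otu_id
    ]
    if len(parents) < 2:
        return BimeraCall(False)
    match = {p.otu_id: _match_profile(query, p.representative, scoring) for p in parents}
    best_single = max(m.sum() for m in match.values()) / L
    if best_single > max_single_identity:
        return BimeraCall(False, best_single_identity=float(best_single))
    best = BimeraCall(False, best_single_identity=float(best_single))
    b = np.arange(1, L)
    for i, pa in enumerate(parents):
        ma = match[pa.otu_id]
        for pb in parents[i + 1:]:
            mb = match[pb.otu_id]
            inf = ma | mb
            tot_inf = int(inf.sum())
            if tot_inf == 0:
                continue
            cum_inf = np.concatenate([[0], np.cumsum(inf)])
            for left, right, pl, pr in ((ma, mb, pa, pb), (mb, ma, pb, pa)):
                cl = np.concatenate([[0], np.cumsum(left)])
                cr = np.concatenate([[0], np.cumsum(right)])
                den_l = cum_inf[1:L]
                den_r = tot_inf - cum_inf[1:L]
                left_id = cl[1:L] / np.maximum(den_l, 1)
                right_id = (cr[L] - cr[1:L]) / np.maximum(den_r, 1)
                ok = (
                    (den_l >= min_segment_columns)
                    & (den_r >= min_segment_columns)
                    & (left_id >= segment_floor)
                    & (right_id >= segment_floor)
                )
                if not ok.any():
                    continue
                split = (cl[1:L] + cr[L] - cr[1:L]) / tot_inf
                split[~ok] = -1.0
                k = int(np.argmax(split))
                if split[k] >= split_identity and split[k] > best.split_identity:
                    best = BimeraCall(
                        flagged=True,
                        parent_a=pl.otu_id,
                        parent_b=pr.otu_id,
                        breakpoint=k + 1,
                        split_identity=float(split[k]),
                        best_single_identity=float(best_single),
                    )
    return best


def end_integrity_screen(
    otu: OtuRecord, best_hit: ReferenceHit | None, max_end_gap: int = 5
) -> bool:
    """Keep iff the best reference alignment reaches within
    ``max_end_gap`` nucleotides of both query ends (no hit at all
    means no reference support: discard)."""
    if best_hit is None:
        return False
    L = best_hit.query_length
    return (best_hit.q_start - 1) <= max_end_gap and (L - best_hit.q_end) <= max_end_gap


def singleton_screen(
    otu: OtuRecord, best_hit: ReferenceHit | None, max_dissimilarity: float = 0.01
) -> bool:
    """Single-read OTUs need a (near-)perfect full-span reference
    match; multi-read OTUs pass unconditionally."""
    if otu.total != 1:
        return True
    if best_hit is None:
        return False
    L = best_hit.query_length
    full_span = best_hit.q_start == 1 and best_hit.q_end == L
    return full_span and (1.0 - best_hit.identity_fraction) <= max_dissimilarity + 1e-12


def _shared_kmer_fraction(a: str, b: str, k: int = 8) -> float:
    def km(s):
        e = encode_dna(s)
        out = set()
        code = 0
        mask = (1 << (2 * k)) - 1
        for i, x in enumerate(e):
            code = ((code << 2) | int(x)) & mask
            if i >= k - 1:
                out.add(code)
        return out

    ka = km(a)
    return len(ka & km(b)) / max(len(ka), 1)


def apply_screens(
    otus: Sequence[OtuRecord],
    reference: Sequence[ReferenceRecord],
    split_identity: float = 0.99,
    max_single_identity: float = 0.95,
    abundance_skew: float = 2.0,
    max_end_gap: int = 5,
    singleton_max_dissim: float = 0.01,
    max_parents: int = 20,
    min_parent_kmer_share: float = 0.10,
    scoring: Scoring = Scoring(),
    external_chimera_ids: Sequence[str] | None = None,
) -> list[dict]:
    """Run chimera -> end-integrity -> singleton screens in sequence,
    setting flags on the records in place.

    ``external_chimera_ids`` bypasses the built-in bimera test with a
    list of OTU ids flagged by an external chimera tool.  Parent search
    is limited to the ``max_parents`` most abundant eligible OTUs that
    share at least ``min_parent_kmer_share`` of the query's 8-mers (a
    pure speed heuristic: a real parent shares at least the breakpoint
    fraction, >= 0.2 by construction of PCR template switching).

    Returns the discard report (otu_id, reason, evidence dicts).
    """
    report = []
    by_total = sorted(otus, key=lambda o: -o.total)
    hits: dict[str, ReferenceHit | None] = {}

    if external_chimera_ids is not None:
        flagged_ids = set(external_chimera_ids)
        for otu in otus:
            if otu.otu_id in flagged_ids:
                otu.flags.add("chimera")
                report.append({"otu_id": otu.otu_id, "reason": "chimera", "evidence": "external"})
    else:
        # queries in decreasing abundance so that parents (which must be
        # at least 2x as abundant) are screened first; OTUs already
        # flagged as chimeric never serve as parents
        for otu in by_total:
            eligible = [
                p
                for p in by_total
                if p.total >= abundance_skew * otu.total
                and p.otu_id != otu.otu_id
                and "chimera" not in p.flags
            ][: max_parents * 3]
            eligible = [
                p
                for p in eligible
                if _shared_kmer_fraction(otu.representative, p.representative)
                >= min_parent_kmer_share
            ][:max_parents]
            call = detect_bimera(
                otu,
                eligible,
                split_identity=split_identity,
                max_single_identity=max_single_identity,
                abundance_skew=abundance_skew,
                scoring=scoring,
            )
            if call.flagged:
                otu.flags.add("chimera")
                report.append(
                    {
                        "otu_id": otu.otu_id,
                        "reason": "chimera",
                        "evidence": f"{call.parent_a}|{call.parent_b}@{call.breakpoint}"
                        f" split={call.split_identity:.3f} single={call.best_single_identity:.3f}",
                    }
                )

    for otu in otus:
        if otu.flags:
            continue
        hit = search_reference(otu.otu_id, otu.representative, reference, scoring)
        hits[otu.otu_id] = hit
        if not end_integrity_screen(otu, hit, max_end_gap):
            otu.flags.add("end_artifact")
            ev = "no_reference_support" if hit is None else f"q_span={hit.q_start}..{hit.q_end}/{hit.query_length}"
            report.append({"otu_id": otu.otu_id, "reason": "end_artifact", "evidence": ev})

    for otu in otus:
        if otu.flags:
            continue
        hit = hits.get(otu.otu_id)
        if not singleton_screen(otu, hit, singleton_max_dissim):
            ev = "no_hit" if hit is None else f"id={hit.identity_fraction:.3f} span={hit.q_start}..{hit.q_end}"
            otu.flags.add("singleton_reject")
            report.append({"otu_id": otu.otu_id, "reason": "singleton_reject", "evidence": ev})
    return report
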