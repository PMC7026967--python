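"""Taxonomy assignment by nearest-reference search.

Each surviving OTU is aligned against an annotated reference set; the
best hit supplies the lineage and the closest-valid-taxon identity
(reported to one decimal, percent).  OTUs under 95% identity to their
closest reference are flagged as likely uncharacterised species.

Rank-level confidence is a consensus over the near-best hits: of the
top-k hits by alignment score whose score reaches ``score_frac``
(default 0.8) of the best and whose identity is within ``margin``
(default 3 identity points) of the best, the fraction agreeing with
the best hit's label at that rank.  The score floor keeps short
spurious local blocks on unrelated references out of the consensus.  Ranks with confidence below 0.8 are
reported as ``unclassified <parent>``.  A pluggable hook accepts an
external classifier table instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from otupipe.align import Scoring, align_local
from otupipe.cluster import CountTable, OtuRecord
from otupipe.screen import ReferenceRecord

__all__ = ["RANKS", "TaxonomyCall", "assign_taxonomy", "aggregate_by_rank", "calls_from_table"]

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class TaxonomyCall:
    otu_id: str
    lineage: tuple[str, ...]  # reported labels phylum -> genus
    confidence: tuple[float, ...]
    closest_taxon: str
    identity_percent: float  # 0-100, one decimal
    novel_flag: bool

    def __post_init__(self):
        if self.novel_flag != (self.identity_percent < 95.0):
            raise ValueError("novel_flag must equal (identity_percent < 95)")


def assign_taxonomy(
    otu: OtuRecord,
    reference: Sequence[ReferenceRecord],
    top_k: int = 10,
    margin: float = 0.03,
    score_frac: float = 0.8,
    min_confidence: float = 0.8,
    scoring: Scoring = Scoring(),
) -> TaxonomyCall:
    """Nearest-reference lineage with rank-level consensus confidence."""
    if not reference:
        raise ValueError("empty reference set")
    query = otu.representative
    scored = []
    for i, rec in enumerate(sorted(reference, key=lambda r: (-len(r.seq), r.id))):
        hit = align_local(query, rec.seq, scoring)
        scored.append((-hit.score, i, hit.identity, rec))
    scored.sort()
    best_score, best_id, best = -scored[0][0], scored[0][2], scored[0][3]
    pool = [
        rec
        for neg, _, ident, rec in scored[:top_k]
        if -neg >= score_frac * best_score and ident >= best_id - margin
    ]

    lineage = []
    confidence = []
    parent = "Bacteria"
    for r, rank in enumerate(RANKS):
        label = best.lineage[r] if r < len(best.lineage) else ""
        agree = sum(1 for rec in pool if r < len(rec.lineage) and rec.lineage[r] == label)
        conf = agree / len(pool)
        confidence.append(conf)
        if label and conf >= min_confidence:
            lineage.append(label)
            parent = label
        else:
            lineage.append(f"unclassified {parent}")
    identity_percent = round(best_id * 100.0, 1)
    return TaxonomyCall(
        otu_id=otu.otu_id,
        lineage=tuple(lineage),
        confidence=tuple(confidence),
        closest_taxon=best.id,
        identity_percent=identity_percent,
        novel_flag=identity_percent < 95.0,
    )


def calls_from_table(path: str) -> dict[str, TaxonomyCall]:
    """Load an external classifier's calls (TSV: otu_id, lineage
    semicolon-joined, closest_taxon, identity_percent)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        ident = round(float(row["identity_percent"]), 1)
        out[row["otu_id"]] = TaxonomyCall(
            otu_id=row["otu_id"],
            lineage=tuple(str(row["lineage"]).split(";")),
            confidence=tuple([np.nan] * len(RANKS)),
            closest_taxon=row.get("closest_taxon", ""),
            identity_percent=ident,
            novel_flag=ident < 95.0,
        )
    return out


def aggregate_by_rank(
    table: CountTable,
    calls: Mapping[str, TaxonomyCall],
    rank: str,
    minor_threshold: float = 0.0,
) -> pd.DataFrame:
    """Collapse the OTU table to relative abundance (%) at a rank.

    Per-sample percentages sum to 100.  With ``minor_threshold`` > 0,
    taxa whose across-sample mean percentage is below the threshold
    are pooled into ``Other <phylum>``.
    """
    if rank not in RANKS:
        raise KeyError(f"rank {rank!r} not in {RANKS}")
    r = RANKS.index(rank)
    missing = [o for o in table.otu_ids if o not in calls]
    if missing:
        raise KeyError(f"OTUs without a taxonomy call: {missing[:5]}")
    rel = table.relative_abundance(percent=True)
    labels = {}
    phyla = {}
    for otu_id in table.otu_ids:
        call = calls[otu_id]
        labels[otu_id] = call.lineage[r]
        phyla[otu_id] = call.lineage[0]
    out = rel.T.groupby(pd.Series(labels)).sum().T
    if minor_threshold > 0:
        label_phylum = {}
        for otu_id, lab in labels.items():
            label_phylum.setdefault(lab, phyla[otu_id])
        minor = out.columns[out.mean(axis=0) < minor_threshold]
        for lab in minor:
            pool = f"Other {label_phylum[lab]}"
            if pool not in out.columns:
                out[pool] = 0.0
            out[pool] += out[lab]
        out = out.drop(columns=list(minor))
    return out
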