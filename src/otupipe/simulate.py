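"""Ground-truthed synthetic communities for the nursery-pig succession study.

Generates four sample sets — CON II, PEP II, CON III, PEP III — whose
compositions emulate the Lactobacillus-dominant Phase II control
profile, the Streptococcus-dominant Phase III profiles, and the
bimodal peptide-treatment Phase II group (each PEP II sample drawn from either
the II-like or the III-like profile with probability 1/2, matching the
split of those samples between the two ordination clusters).

Per-sample composition is Dirichlet-multinomial: p ~ Dirichlet(c * m)
with group means m and concentration c (default 5, chosen so that the
simulated between-animal SEM at n = 10 is on the scale of the study's
family-level SEMs); counts ~ Multinomial(reads_per_sample, p).

Reads are the taxon's primered reference sequence with i.i.d.
substitution errors confined to the biological insert (primer sites
stay intact so that read-screen ground truth is exact).  Configurable
fractions of reads are replaced by two-parent chimeras (single
breakpoint uniform in the middle 60% of the sequence), interior-
truncated (< min length) or interior-elongated (> max length) reads,
and reads planted with > 1% of bases below Phred 15.  All planted
ground truth is written to a sidecar table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from otupipe.cluster import CountTable
from otupipe.qc import FORWARD_PRIMER, REVERSE_PRIMER, Read, reverse_complement

__all__ = [
    "GROUPS",
    "TaxonProfile",
    "SimConfig",
    "SimulatedReads",
    "default_profiles",
    "simulate_counts",
    "simulate_reads",
    "write_reference_fasta",
]

GROUPS = ("CON II", "PEP II", "CON III", "PEP III")

_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class TaxonProfile:
    """One simulated taxon: primered V1-V3-like reference sequence,
    lineage (phylum -> genus) and per-group mean relative abundance.

    ``reference_identity`` is the identity between this taxon's true
    sequence and its closest entry in the taxonomy reference set;
    values below 0.95 emulate OTUs from uncharacterised species whose
    best database match is a different, related organism.
    """

    name: str
    reference_sequence: str
    lineage: tuple[str, ...]
    group_means: dict[str, float]
    reference_identity: float = 1.0

    @property
    def insert(self) -> str:
        """Reference sequence with both primer flanks removed."""
        return self.reference_sequence[
            len(FORWARD_PRIMER): len(self.reference_sequence) - len(REVERSE_PRIMER)
        ]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the read simulator; defaults are the study conditions
    (4 groups x 10 animals, 5000 reads per sample)."""

    n_samples_per_group: int = 10
    reads_per_sample: int = 5000
    overdispersion: float = 5.0  # Dirichlet concentration c
    error_rate: float = 0.005  # per-base substitution probability
    chimera_fraction: float = 0.02
    short_fraction: float = 0.02
    long_fraction: float = 0.02
    low_quality_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self):
        for name in ("chimera_fraction", "short_fraction", "long_fraction", "low_quality_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion (Dirichlet concentration) must be > 0")
        if self.n_samples_per_group < 1 or self.reads_per_sample < 1:
            raise ValueError("need at least one sample and one read")


# (name, phylum, class, order, family, genus, CON II, CON III, PEP III,
#  reference identity): group means per column sum to 1; the PEP II
# profile is the 50:50 CON II / CON III mixture realised at sample
# level.  Family masses: Lactobacillaceae .448/.130/.160,
# Streptococcaceae .021/.322/.256, mirroring the printed family table.
_TAXA = [
    ("Lb_amylovorus_like", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.001, 0.104, 0.120, 0.99),
    ("Lb_gasseri_like", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.319, 0.003, 0.008, 0.99),
    ("Lb_reuteri_like", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.026, 0.001, 0.002, 0.99),
    ("Lb_taiwanensis_like", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.031, 0.002, 0.001, 0.95),
    ("Lb_reuteri_minor_like", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.010, 0.001, 0.001, 0.95),
    ("Lb_uncharacterised", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", 0.061, 0.019, 0.028, 0.88),
    ("St_macedonicus_like", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", 0.013, 0.262, 0.207, 0.95),
    ("St_alactolyticus_like", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", 0.004, 0.026, 0.026, 0.96),
    ("St_uncharacterised_a", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", 0.002, 0.017, 0.019, 0.90),
    ("St_uncharacterised_b", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", 0.002, 0.017, 0.004, 0.91),
    ("Cl_saccharo_like", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium", 0.059, 0.118, 0.189, 0.97),
    ("Ro_faecis_like", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia", 0.132, 0.078, 0.059, 0.98),
    ("Pr_copri_like", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", 0.140, 0.160, 0.118, 0.98),
    ("Me_indica_like", "Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Megasphaera", 0.005, 0.034, 0.031, 0.98),
    ("Te_mayombei_like", "Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Terrisporobacter", 0.195, 0.158, 0.187, 0.97),
]

_PROFILE_SEED = 191716  # fixed: default_profiles() is a deterministic object


def default_profiles() -> list[TaxonProfile]:
    """The default 15-taxon community (7 families, 2 phyla).

    Reference sequences are synthetic random DNA flanked by the 27F
    primer and the reverse complement of 519R (total 438-498 nt), so
    that distinct taxa are far beyond the 5% OTU cutoff from each
    other; real reference sequences can be swapped in by constructing
    :class:`TaxonProfile` objects from a FASTA instead.
    """
    rng = np.random.default_rng(_PROFILE_SEED)
    rc_rev = reverse_complement(REVERSE_PRIMER)
    profiles = []
    for row in _TAXA:
        name, phylum, cls, order, family, genus = row[:6]
        con2, con3, pep3 = row[6:9]
        ref_id = row[9]
        insert_len = int(rng.integers(400, 461))
        insert = "".join(rng.choice(list("ACGT"), insert_len))
        seq = FORWARD_PRIMER + insert + rc_rev
        means = {
            "CON II": con2,
            "PEP II": 0.5 * (con2 + con3),
            "CON III": con3,
            "PEP III": pep3,
        }
        profiles.append(
            TaxonProfile(
                name=name,
                reference_sequence=seq,
                lineage=(phylum, cls, order, family, genus),
                group_means=means,
                reference_identity=ref_id,
            )
        )
    for group in GROUPS:
        total = sum(p.group_means[group] for p in profiles)
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"group {group} means sum to {total}")
    return profiles


def _sample_ids(config: SimConfig) -> list[tuple[str, str]]:
    out = []
    for group in GROUPS:
        tag = group.replace(" ", "")
        for i in range(config.n_samples_per_group):
            out.append((f"{tag}-{i + 1:02d}", group))
    return out


def simulate_counts(
    profiles: Sequence[TaxonProfile], config: SimConfig
) -> tuple[CountTable, pd.DataFrame]:
    """Draw per-sample taxon counts.

    Returns the samples x taxa :class:`CountTable` and the true
    per-sample proportions used for each multinomial draw (the ground
    truth for parameter-recovery tests).  PEP II samples are bimodal:
    each is assigned the CON II-like or CON III-like profile with
    probability 1/2.
    """
    if config.overdispersion <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(config.seed)
    names = [p.name for p in profiles]
    rows, truth = [], []
    sample_meta = dict(_sample_ids(config))
    for sample, group in sample_meta.items():
        if group == "PEP II":
            source = "CON II" if rng.random() < 0.5 else "CON III"
        else:
            source = group
        means = np.array([p.group_means[source] for p in profiles])
        alpha = config.overdispersion * means
        # taxa absent from a profile stay absent in the sample
        p = np.zeros(len(means))
        pos = alpha > 0
        p[pos] = rng.dirichlet(alpha[pos])
        counts = rng.multinomial(config.reads_per_sample, p)
        rows.append(counts)
        truth.append(p)
    counts = pd.DataFrame(rows, index=list(sample_meta), columns=names)
    truth = pd.DataFrame(truth, index=list(sample_meta), columns=names)
    return CountTable(counts, sample_meta), truth


@dataclass
class SimulatedReads:
    """Reads plus planted ground truth (one row per read in sidecar:
    read_id, sample, taxon, is_chimera, parent_a, parent_b, violation)."""

    reads_by_sample: dict[str, list[Read]]
    sidecar: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, reads in self.reads_by_sample.items():
            with open(out_dir / f"{sample}.fastq", "w") as fh:
                for r in reads:
                    qual = "".join(chr(q + 33) for q in r.quals)
                    fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
        self.sidecar.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)


def _mutate(seq: str, n_subs: int, rng: np.random.Generator, lo: int, hi: int) -> str:
    """Plant exactly n_subs substitutions at distinct positions in [lo, hi)."""
    if n_subs == 0:
        return seq
    pos = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + 1 + rng.integers(3)) % 4]
    return "".join(out)


def simulate_reads(
    counts: CountTable,
    profiles: Sequence[TaxonProfile],
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> SimulatedReads:
    """Emit per-sample reads for a count table drawn by
    :func:`simulate_counts`, with artifact fractions planted exactly
    (``round(fraction * reads)`` reads per sample and artifact class)."""
    rng = np.random.default_rng(config.seed + 1)
    by_name = {p.name: p for p in profiles}
    fwd_len = len(FORWARD_PRIMER)
    rev_len = len(REVERSE_PRIMER)
    reads_by_sample: dict[str, list[Read]] = {}
    sidecar_rows = []
    for sample in counts.samples:
        row = counts.counts.loc[sample]
        taxa = [name for name in row.index for _ in range(int(row[name]))]
        n = len(taxa)
        order = rng.permutation(n)
        n_ch = round(config.chimera_fraction * n)
        n_sh = round(config.short_fraction * n)
        n_lo = round(config.long_fraction * n)
        n_lq = round(config.low_quality_fraction * n)
        kinds = ["normal"] * n
        k = 0
        for kind, cnt in (("chimera", n_ch), ("short", n_sh), ("long", n_lo), ("lowq", n_lq)):
            for _ in range(cnt):
                if k < n:
                    kinds[order[k]] = kind
                    k += 1
        present = [name for name in row.index if row[name] > 0]
        weights = np.array([row[name] for name in present], dtype=float)
        weights /= weights.sum()
        reads = []
        for idx in range(n):
            kind = kinds[idx]
            read_id = f"{sample}_r{idx:06d}"
            taxon = taxa[idx]
            parent_a = parent_b = ""
            violation = "none"
            is_chimera = False
            if kind == "chimera" and len(present) >= 2:
                pa, pb = rng.choice(len(present), size=2, replace=False, p=weights)
                parent_a, parent_b = present[pa], present[pb]
                sa, sb = by_name[parent_a].reference_sequence, by_name[parent_b].reference_sequence
                u = rng.uniform(0.2, 0.8)
                bases = sa[: round(u * len(sa))] + sb[round(u * len(sb)):]
                is_chimera = True
                taxon = ""
            else:
                bases = by_name[taxon].reference_sequence
            L = len(bases)
            if kind == "short":
                # remove interior bases, keeping both primer sites intact
                keep = 360 - fwd_len - rev_len
                bases = bases[: fwd_len + keep // 2] + bases[L - rev_len - keep // 2:]
                violation = "too_short"
            elif kind == "long":
                ins = "".join(rng.choice(list("ACGT"), 600 - L))
                mid = L // 2
                bases = bases[:mid] + ins + bases[mid:]
                violation = "too_long"
            L = len(bases)
            # substitution errors, confined to the insert
            if config.error_rate > 0:
                n_err = rng.binomial(L - fwd_len - rev_len, config.error_rate)
                bases = _mutate(bases, int(n_err), rng, fwd_len, L - rev_len)
            quals = np.asarray(rng.integers(35, 41, size=L))
            if kind == "lowq":
                n_bad = math.ceil(0.02 * L)
                bad = rng.choice(L, size=n_bad, replace=False)
                quals[bad] = rng.integers(8, 15, size=n_bad)
                violation = "low_quality"
            reads.append(Read(read_id, bases, tuple(int(q) for q in quals)))
            sidecar_rows.append(
                (read_id, sample, taxon, is_chimera, parent_a, parent_b, violation)
            )
        reads_by_sample[sample] = reads
    sidecar = pd.DataFrame(
        sidecar_rows,
        columns=["read_id", "sample", "taxon", "is_chimera", "parent_a", "parent_b", "violation"],
    )
    sim = SimulatedReads(reads_by_sample, sidecar)
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def write_reference_fasta(
    profiles: Sequence[TaxonProfile], path: str | Path, seed: int = _PROFILE_SEED
) -> None:
    """Write the annotated taxonomy reference set (``>id lineage``).

    For taxa with ``reference_identity`` < 1 the database entry is a
    mutated copy of the true sequence (substitutions planted in the
    insert at rate 1 - identity), emulating an uncharacterised species
    whose closest valid taxon is a related organism.
    """
    rng = np.random.default_rng(seed + 7)
    rc_len = len(REVERSE_PRIMER)
    with open(path, "w") as fh:
        for p in profiles:
            seq = p.reference_sequence
            if p.reference_identity < 1.0:
                L = len(seq)
                n_sub = round((1.0 - p.reference_identity) * (L - len(FORWARD_PRIMER) - rc_len))
                seq = _mutate(seq, n_sub, rng, len(FORWARD_PRIMER), L - rc_len)
            lineage = ";".join(p.lineage)
            fh.write(f">{p.name}_ref {lineage}\n{seq}\n")
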