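"""File formats: FASTQ/FASTA, mothur-style ``shared`` tables, metadata.

The ``shared`` dialect is the tab-separated OTU table mothur emits:
header ``label Group numOtus <otu ids...>``, one row per sample with
the clustering label (the distance cutoff) in the first column.
Count round-trips through write/read are lossless.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from otupipe.cluster import CountTable, OtuRecord
from otupipe.qc import Read
from otupipe.screen import ReferenceRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_reference_fasta",
    "read_metadata",
    "write_shared",
    "read_shared",
]


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[Read]:
    """Read a (possibly gzipped) Phred+33 FASTQ file; malformed records
    are reported with an approximate line number."""
    reads = []
    with _open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ValueError("Lengths of sequence and quality values differs")
                reads.append(
                    Read(title.split()[0], seq, tuple(ord(c) - 33 for c in qual))
                )
        except ValueError as err:
            line = 4 * len(reads) + 1
            raise ValueError(f"{path}: malformed FASTQ near line {line}: {err}") from err
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Returns (id, description, sequence) triples."""
    out = []
    name = None
    desc = ""
    chunks: list[str] = []
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, desc, "".join(chunks)))
                fields = line[1:].split(None, 1)
                name = fields[0] if fields else ""
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        out.append((name, desc, "".join(chunks)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (id-or-header, sequence) pairs."""
    with _open(path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Annotated reference set: ``>id lineage`` with a semicolon-joined
    lineage string in the description."""
    recs = []
    for name, desc, seq in read_fasta(path):
        lineage = tuple(x.strip() for x in desc.split(";") if x.strip()) if desc else ()
        recs.append(ReferenceRecord(name, seq.upper(), lineage))
    if not recs:
        raise ValueError(f"no sequences in reference FASTA {path}")
    return recs


def read_metadata(path: str | Path) -> dict[str, str]:
    """Sample -> group TSV (optional header line 'sample<TAB>group')."""
    out: dict[str, str] = {}
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>group'")
            if ln == 1 and parts[0].lower() == "sample":
                continue
            out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"no samples in metadata {path}")
    return out


def write_shared(table: CountTable, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        otus = table.otu_ids
        fh.write("label\tGroup\tnumOtus\t" + "\t".join(otus) + "\n")
        for s in table.samples:
            row = table.counts.loc[s]
            fh.write(
                f"{table.label}\t{s}\t{len(otus)}\t" + "\t".join(str(int(v)) for v in row) + "\n"
            )


def read_shared(path: str | Path, metadata: Mapping[str, str] | None = None) -> CountTable:
    df = pd.read_csv(path, sep="\t")
    required = ["label", "Group", "numOtus"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: not a shared file (header must start with {required})")
    label = str(df["label"].iloc[0])
    counts = df.drop(columns=required)
    counts.index = df["Group"].astype(str)
    counts.index.name = None
    groups = dict(metadata) if metadata else {s: "NA" for s in counts.index}
    return CountTable(counts, groups, label)
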