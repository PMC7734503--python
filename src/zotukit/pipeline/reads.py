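"""Read records and FASTQ/FASTA input-output (Sanger Phred+33)."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
from Bio import SeqIO

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def revcomp(sequence: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred quality scores."""

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise ValueError(f"{self.read_id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Iterate over a FASTQ file (plain or gzip), uppercasing sequences."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.array(
                    rec.letter_annotations["phred_quality"], dtype=np.int64
                ),
            )


def write_zotu_fasta(zotus: Sequence, path: Union[str, Path]) -> None:
    """Write ZOTUs with ``>Zotu<N>;size=<abundance>`` headers."""
    with open(path, "w") as handle:
        for z in zotus:
            handle.write(f">{z.zotu_id};size={z.abundance}\n{z.sequence}\n")


def parse_size_header(header: str) -> tuple[str, int]:
    """Parse a ``label;size=<n>`` FASTA header into (label, abundance)."""
    fields = header.split(";")
    label = fields[0]
    for f in fields[1:]:
        if f.startswith("size="):
            return label, int(f[5:])
    raise ValueError(f"no size= annotation in header {header!r}")


def read_zotu_fasta(path: Union[str, Path]) -> list[tuple[str, str, int]]:
    """Read a ``;size=`` FASTA into (label, sequence, abundance) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label, size = parse_size_header(rec.description)
        out.append((label, str(rec.seq).upper(), size))
    return out
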