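"""Taxonomy-based contamination filter against a lineage-bearing FASTA.

Reference headers follow the dialect
``accession|k__...;p__...;c__...;o__...;f__...;g__...;s__...|SH-id``.
Each ZOTU is aligned against every reference; the best hit is the
maximum percent identity (ties resolved by reference order).  A ZOTU is
kept when its best identity reaches the threshold (default 70%) and the
best hit's kingdom is Fungi.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from ._align import identity_percent
from .denoise import ZotuRecord

alignment_identity = identity_percent

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class Lineage:
    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse ``k__Fungi;p__...;...;s__...`` into a 7-rank lineage."""
        values = {}
        parts = [p.strip() for p in text.split(";") if p.strip()]
        if len(parts) != 7:
            raise ValueError(f"expected 7 lineage ranks, got {len(parts)}: {text!r}")
        for rank, prefix, part in zip(RANKS, _RANK_PREFIXES, parts):
            if not part.startswith(prefix):
                raise ValueError(f"rank {rank} missing prefix {prefix} in {text!r}")
            values[rank] = part[len(prefix):]
        return cls(**values)

    def to_string(self) -> str:
        return ";".join(
            prefix + getattr(self, rank)
            for rank, prefix in zip(RANKS, _RANK_PREFIXES)
        )

    def rank(self, name: str) -> str:
        key = "class_" if name == "class" else name
        if key not in RANKS:
            valid = [r.rstrip("_") for r in RANKS]
            raise ValueError(f"unknown rank {name!r}; valid ranks: {valid}")
        return getattr(self, key)


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    lineage: Lineage
    sh_id: str
    sequence: str


@dataclass(frozen=True)
class TaxonAssignment:
    lineage: Lineage
    best_hit_name: str
    identity: float


def parse_reference_header(header: str) -> tuple[str, Lineage, str]:
    """Parse a reference header; hard error naming the record on failure."""
    fields = header.split("|")
    if len(fields) != 3:
        raise ValueError(
            f"unparseable reference header {header!r}: "
            "expected accession|lineage|SH-id"
        )
    accession, lineage_text, sh_id = fields
    try:
        lineage = Lineage.from_string(lineage_text)
    except ValueError as exc:
        raise ValueError(f"unparseable lineage in record {accession!r}: {exc}") from exc
    return accession, lineage, sh_id


def load_reference_fasta(path: Union[str, Path]) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, lineage, sh_id = parse_reference_header(rec.description)
        records.append(
            ReferenceRecord(
                accession=accession,
                lineage=lineage,
                sh_id=sh_id,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def best_hit(
    sequence: str, references: Sequence[ReferenceRecord]
) -> tuple[Optional[ReferenceRecord], float]:
    """Best reference by percent identity (first in reference order on ties)."""
    best_ref: Optional[ReferenceRecord] = None
    best_identity = -1.0
    for ref in references:
        identity = identity_percent(sequence, ref.sequence)
        if identity > best_identity:
            best_ref, best_identity = ref, identity
    return best_ref, max(best_identity, 0.0)


def taxonomy_filter(
    zotus: Sequence[ZotuRecord],
    references: Sequence[ReferenceRecord],
    min_identity: float = 70.0,
    kingdom: str = "Fungi",
) -> tuple[list[tuple[ZotuRecord, TaxonAssignment]], list[ZotuRecord]]:
    """Partition ZOTUs into kept (with assignment) and discarded."""
    if not references:
        raise ValueError("reference database is empty")
    kept: list[tuple[ZotuRecord, TaxonAssignment]] = []
    discarded: list[ZotuRecord] = []
    for zotu in zotus:
        ref, identity = best_hit(zotu.sequence, references)
        if ref is not None and identity >= min_identity and ref.lineage.kingdom == kingdom:
            kept.append(
                (
                    zotu,
                    TaxonAssignment(
                        lineage=ref.lineage,
                        best_hit_name=ref.accession,
                        identity=identity,
                    ),
                )
            )
        else:
            discarded.append(zotu)
    return kept, discarded
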