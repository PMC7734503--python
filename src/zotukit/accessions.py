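"""Mining of sequence-archive accession identifiers from publication text.

Accessions are recognised by a fixed set of archive prefixes.  A match
requires the prefix followed by 4-9 digits with non-alphanumeric (or
string) boundaries on both sides, which rejects prefixes embedded inside
words ("surplus") and digit-less prefix mentions ("the SRA archive").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

#: prefix class -> archive name.  SRR shares the SRA namespace with the
#: study/sample/experiment prefixes even though run accessions are
#: normally reached through their experiment.
PREFIX_ARCHIVE: dict[str, str] = {
    "SRA": "SRA",
    "SRP": "SRA",
    "SRS": "SRA",
    "SRX": "SRA",
    "SRR": "SRA",
    "PRJNA": "BioProject",
    "PRJEB": "BioProject",
    "ERP": "ENA",
    "ERS": "ENA",
}

PREFIX_CLASSES: tuple[str, ...] = tuple(PREFIX_ARCHIVE)

# Longest prefix first so PRJNA/PRJEB win over any shorter alternative
# at the same position.
_ALTERNATION = "|".join(sorted(PREFIX_ARCHIVE, key=len, reverse=True))
ACCESSION_RE = re.compile(
    r"(?<![A-Za-z0-9])(" + _ALTERNATION + r")(\d{4,9})(?![A-Za-z0-9])"
)


@dataclass(frozen=True)
class AccessionMatch:
    """One archive identifier found in text."""

    accession: str
    prefix_class: str
    archive: str
    char_offset: int

    def __post_init__(self) -> None:
        if self.prefix_class not in PREFIX_ARCHIVE:
            raise ValueError(f"unknown prefix class {self.prefix_class!r}")
        if self.archive != PREFIX_ARCHIVE[self.prefix_class]:
            raise ValueError(
                f"{self.prefix_class} belongs to {PREFIX_ARCHIVE[self.prefix_class]}, "
                f"not {self.archive}"
            )
        if self.char_offset < 0:
            raise ValueError("char_offset must be >= 0")


@dataclass
class PublicationRecord:
    """A publication as plain text, plus its standard identifiers."""

    doi: str
    title: str = ""
    pmid: Optional[str] = None
    abstract: Optional[str] = None
    body_text: str = ""

    def __post_init__(self) -> None:
        if not self.doi:
            raise ValueError("doi must be non-empty")


@dataclass
class MappingResult:
    """Outcome of mapping a publication to archive studies.

    ``rejected`` lists structured cross-references whose accession fits
    no known prefix class; they are reported, never silently dropped.
    """

    matches: list[AccessionMatch] = field(default_factory=list)
    rejected: list[tuple[str, str, str]] = field(default_factory=list)


def extract_accessions(text: str) -> list[AccessionMatch]:
    """Return all accession matches in ``text``, ordered by offset.

    Duplicate accessions at different offsets are all reported.
    """
    return [
        AccessionMatch(
            accession=m.group(0),
            prefix_class=m.group(1),
            archive=PREFIX_ARCHIVE[m.group(1)],
            char_offset=m.start(),
        )
        for m in ACCESSION_RE.finditer(text)
    ]


def classify_accession(accession: str) -> Optional[str]:
    """Return the prefix class of a bare accession string, or None."""
    m = ACCESSION_RE.fullmatch(accession)
    return m.group(1) if m else None


def map_publication_to_studies(
    pub: PublicationRecord,
    databank_refs: Sequence[tuple[str, str]] = (),
) -> MappingResult:
    """Map a publication to archive accessions.

    Structured cross-references (the databank list a publication-record
    adapter supplies) take precedence; full-text mining is the fallback
    when none are given.  The result is deduplicated by accession string.
    """
    result = MappingResult()
    seen: set[str] = set()
    if databank_refs:
        for archive_name, accession in databank_refs:
            prefix = classify_accession(accession)
            if prefix is None:
                result.rejected.append(
                    (archive_name, accession, "accession fits no known prefix class")
                )
                continue
            if accession in seen:
                continue
            seen.add(accession)
            offset = pub.body_text.find(accession)
            result.matches.append(
                AccessionMatch(
                    accession=accession,
                    prefix_class=prefix,
                    archive=PREFIX_ARCHIVE[prefix],
                    char_offset=offset if offset >= 0 else 0,
                )
            )
        return result
    for match in extract_accessions(pub.body_text):
        if match.accession in seen:
            continue
        seen.add(match.accession)
        result.matches.append(match)
    return result


def expand_run_range(start: str, end: str) -> list[str]:
    """Expand an accession range like SRR1502225..SRR1502736.

    Explicit utility, off by default in mining: a typographic dash
    between two accessions does not always denote a range.
    """
    ms, me = ACCESSION_RE.fullmatch(start), ACCESSION_RE.fullmatch(end)
    if ms is None or me is None:
        raise ValueError("range endpoints must be valid accessions")
    if ms.group(1) != me.group(1):
        raise ValueError("range endpoints must share a prefix class")
    lo, hi = int(ms.group(2)), int(me.group(2))
    if hi < lo:
        raise ValueError("range end precedes range start")
    width = len(ms.group(2))
    return [f"{ms.group(1)}{i:0{width}d}" for i in range(lo, hi + 1)]
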