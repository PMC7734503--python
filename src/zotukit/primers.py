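"""Primer reference table and primer resolution from experiment designs.

The bundled table lists universal ITS amplicon primers with their
sequences, the subunit marker they amplify, their orientation and known
alias spellings.  ``resolve_primers`` scans free-text experiment-design
descriptions for primer mentions and returns the forward/reverse pair.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerRecord:
    name: str
    sequence: str
    marker: str  # ITS1 | ITS2
    direction: str  # forward | reverse
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class ResolvedPrimers:
    fwd_name: str
    fwd_sequence: str
    rev_name: str
    rev_sequence: str
    marker: str


def bundled_primer_path() -> Path:
    return Path(str(resources.files("zotukit.data") / "primers.tsv"))


def load_primer_table(path: Union[str, Path, None] = None) -> list[PrimerRecord]:
    """Load the primer reference TSV (bundled table by default)."""
    path = bundled_primer_path() if path is None else Path(path)
    records: list[PrimerRecord] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            aliases = tuple(
                a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
            )
            records.append(
                PrimerRecord(
                    name=row["name"],
                    sequence=row["sequence"].upper(),
                    marker=row["marker"],
                    direction=row["direction"],
                    aliases=aliases,
                )
            )
    return records


def _mention_pattern(table: Sequence[PrimerRecord]) -> re.Pattern[str]:
    tokens = sorted(
        {p.name for p in table} | {a for p in table for a in p.aliases},
        key=len,
        reverse=True,
    )
    alternation = "|".join(re.escape(t) for t in tokens)
    return re.compile(
        r"(?<![A-Za-z0-9])(" + alternation + r")(?![A-Za-z0-9])", re.IGNORECASE
    )


def resolve_primers(
    design_text: str,
    table: Optional[Sequence[PrimerRecord]] = None,
) -> Optional[ResolvedPrimers]:
    """Resolve the primer pair mentioned in a design description.

    Matching is case-insensitive on primer names and aliases.  Returns
    None when fewer than two primer mentions are found, when the pair is
    ambiguous (>=2 forward or >=2 reverse candidates) or when the two
    primers amplify different markers; ambiguity is logged.
    """
    if table is None:
        table = load_primer_table()
    if not design_text:
        return None
    by_token = {p.name.casefold(): p for p in table}
    for p in table:
        for alias in p.aliases:
            by_token[alias.casefold()] = p

    mentioned: list[PrimerRecord] = []
    for m in _mention_pattern(table).finditer(design_text):
        primer = by_token[m.group(1).casefold()]
        if primer not in mentioned:
            mentioned.append(primer)
    if len(mentioned) < 2:
        return None

    forwards = [p for p in mentioned if p.direction == "forward"]
    reverses = [p for p in mentioned if p.direction == "reverse"]
    if len(forwards) != 1 or len(reverses) != 1:
        logger.warning(
            "ambiguous primer mentions in design (%d forward, %d reverse): %s",
            len(forwards),
            len(reverses),
            [p.name for p in mentioned],
        )
        return None
    fwd, rev = forwards[0], reverses[0]
    if fwd.marker != rev.marker:
        logger.warning(
            "primer pair %s/%s amplifies conflicting markers %s/%s",
            fwd.name,
            rev.name,
            fwd.marker,
            rev.marker,
        )
        return None
    return ResolvedPrimers(
        fwd_name=fwd.name,
        fwd_sequence=fwd.sequence,
        rev_name=rev.name,
        rev_sequence=rev.sequence,
        marker=fwd.marker,
    )
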