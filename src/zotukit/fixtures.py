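"""Seeded generators for synthetic inputs with ground-truth bookkeeping.

Everything the other modules consume -- FASTQ libraries, lineage-bearing
reference FASTA, publication text with planted accessions, raw metadata
tables -- can be generated here with a known truth table, so the whole
framework is testable without downloading anything.  Every generator is
a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .accessions import PREFIX_ARCHIVE
from .pipeline._align import edit_distance, identity_percent
from .pipeline.reads import revcomp
from .pipeline.trim import IUPAC

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def concretize_primer(primer: str) -> str:
    """Replace IUPAC ambiguity codes by their first allowed base."""
    return "".join(IUPAC[b.upper()][0] for b in primer)


def mutate(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Inject substitution errors at ``rate`` per base; returns the
    mutated sequence and the error positions."""
    if rate <= 0:
        return seq, []
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, []
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars), [int(i) for i in hits]


def random_zotus(
    n: int,
    length: int,
    min_distance: int,
    rng: Union[np.random.Generator, int],
) -> list[str]:
    """Random DNA sequences with pairwise edit distance >= min_distance."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    zotus: list[str] = []
    attempts = 0
    while len(zotus) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("cannot satisfy the pairwise-distance constraint")
        candidate = _random_seq(rng, length)
        if all(edit_distance(candidate, z) >= min_distance for z in zotus):
            zotus.append(candidate)
    return zotus


# --------------------------------------------------------------------------
# FASTQ library


@dataclass
class SyntheticLibrarySpec:
    true_zotus: list[str]
    reads_per_zotu: int = 200
    per_base_error_rate: float = 0.0
    quality: int = 30
    read_length: int = 200
    paired: bool = True
    fwd_primer: str = "GTGARTCATCGAATCTTTG"
    rev_primer: str = "TCCTCCGCTTATTGATATGC"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.true_zotus)) != len(self.true_zotus):
            raise ValueError("true_zotus must be pairwise distinct")
        if not (0.0 <= self.per_base_error_rate < 1.0):
            raise ValueError("error rate must be in [0, 1)")


@dataclass
class SyntheticLibrary:
    fwd_path: Path
    rev_path: Optional[Path]
    truth: pd.DataFrame  # read_id, zotu_index, n_errors
    amplicons: list[str]


def _write_fastq(path: Path, records: Sequence[tuple[str, str]], quality: int) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as handle:
        for read_id, seq in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


def make_fastq(spec: SyntheticLibrarySpec, out_dir: Union[str, Path]) -> SyntheticLibrary:
    """Generate FASTQ file(s) and a truth table for a planted library.

    Reads carry the configured primers at the correct ends; paired mode
    emits overlapping mates.  Byte-identical output under a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    fwd_p = concretize_primer(spec.fwd_primer)
    rev_p = concretize_primer(spec.rev_primer)
    amplicons = [fwd_p + z + revcomp(rev_p) for z in spec.true_zotus]

    fwd_records: list[tuple[str, str]] = []
    rev_records: list[tuple[str, str]] = []
    truth_rows = []
    for zi, amplicon in enumerate(amplicons):
        for ri in range(spec.reads_per_zotu):
            read_id = f"zotu{zi}_read{ri}"
            if spec.paired:
                r1_tpl = amplicon[: spec.read_length]
                r2_tpl = revcomp(amplicon)[: spec.read_length]
                r1, e1 = mutate(r1_tpl, spec.per_base_error_rate, rng)
                r2, e2 = mutate(r2_tpl, spec.per_base_error_rate, rng)
                fwd_records.append((read_id, r1))
                rev_records.append((read_id, r2))
                truth_rows.append(
                    {"read_id": read_id, "zotu_index": zi, "n_errors": len(e1) + len(e2)}
                )
            else:
                read, errs = mutate(amplicon, spec.per_base_error_rate, rng)
                fwd_records.append((read_id, read))
                truth_rows.append(
                    {"read_id": read_id, "zotu_index": zi, "n_errors": len(errs)}
                )

    if spec.paired:
        fwd_path = out_dir / "reads_R1.fastq"
        rev_path = out_dir / "reads_R2.fastq"
        _write_fastq(fwd_path, fwd_records, spec.quality)
        _write_fastq(rev_path, rev_records, spec.quality)
    else:
        fwd_path = out_dir / "reads.fastq"
        rev_path = None
        _write_fastq(fwd_path, fwd_records, spec.quality)
    return SyntheticLibrary(
        fwd_path=fwd_path,
        rev_path=rev_path,
        truth=pd.DataFrame(truth_rows),
        amplicons=amplicons,
    )


# --------------------------------------------------------------------------
# reference FASTA

_FUNGAL_PHYLA = (
    "Basidiomycota",
    "Ascomycota",
    "Mortierellomycota",
    "Mucoromycota",
    "Chytridiomycota",
)
_FUNGAL_FAMILIES = (
    "Russulaceae",
    "Amanitaceae",
    "Boletaceae",
    "Mortierellaceae",
    "Nectriaceae",
)
_OUTGROUP_LINEAGE = (
    "k__Viridiplantae;p__Streptophyta;c__Magnoliopsida;o__Fagales;"
    "f__Fagaceae;g__Quercus;s__Quercus_robur"
)


def fungal_lineage(i: int) -> str:
    phylum = _FUNGAL_PHYLA[i % len(_FUNGAL_PHYLA)]
    family = _FUNGAL_FAMILIES[i % len(_FUNGAL_FAMILIES)]
    return (
        f"k__Fungi;p__{phylum};c__Class{i};o__Order{i};"
        f"f__{family};g__Genus{i};s__Genus{i}_sp"
    )


def make_reference_fasta(
    true_zotus: Sequence[str],
    path: Union[str, Path],
    n_fungal: Optional[int] = None,
    n_outgroup: int = 2,
    seed: int = 0,
    decoy_max_identity: float = 70.0,
) -> list[tuple[str, str]]:
    """Write a lineage-bearing reference FASTA containing the true ZOTUs
    (fungal lineages) plus non-fungal decoys.

    Decoys are verified at generation to stay below
    ``decoy_max_identity`` percent identity against every true ZOTU.
    Returns the (header, sequence) records written.
    """
    n_fungal = len(true_zotus) if n_fungal is None else n_fungal
    if n_fungal < len(true_zotus):
        raise ValueError("n_fungal must cover the true ZOTUs")
    rng = np.random.default_rng(seed)
    length = len(true_zotus[0]) if true_zotus else 250

    records: list[tuple[str, str]] = []
    for i, zotu in enumerate(true_zotus):
        header = f"REF{i:05d}|{fungal_lineage(i)}|SH{i:07d}.07FU"
        records.append((header, zotu))
    for i in range(len(true_zotus), n_fungal):
        header = f"REF{i:05d}|{fungal_lineage(i)}|SH{i:07d}.07FU"
        records.append((header, _random_seq(rng, length)))
    for j in range(n_outgroup):
        attempts = 0
        while True:
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("cannot generate a sufficiently distant decoy")
            decoy = _random_seq(rng, length)
            if all(
                identity_percent(decoy, z) < decoy_max_identity for z in true_zotus
            ):
                break
        header = f"OUT{j:05d}|{_OUTGROUP_LINEAGE}|SH9{j:06d}.07FU"
        records.append((header, decoy))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n{seq}\n")
    return records


# --------------------------------------------------------------------------
# publication corpus and raw metadata


@dataclass
class CorpusTruth:
    text: str
    planted: list[tuple[str, str, int]]  # (accession, prefix_class, offset)
    decoys: list[str]  # substrings that must NOT be reported


@dataclass
class MetadataTruth:
    raw: pd.DataFrame  # columns as deposited
    expected: pd.DataFrame  # per-srs expected curated values (None = absent)


def make_corpus(seed: int = 0) -> CorpusTruth:
    """Publication-style text planting one accession per prefix class
    amid decoy substrings (in-word prefixes, digit-less prefixes)."""
    rng = np.random.default_rng(seed)
    planted: list[tuple[str, str, int]] = []
    parts: list[str] = []
    offset = 0

    def emit(chunk: str) -> None:
        nonlocal offset
        parts.append(chunk)
        offset += len(chunk)

    emit("Raw reads from this survey of surplus forest plots were deposited ")
    emit("in the public archives. ")
    for prefix in PREFIX_ARCHIVE:
        digits = f"{rng.integers(10**5, 10**6):06d}"
        accession = f"{prefix}{digits}"
        emit("Data are available under accession ")
        planted.append((accession, prefix, offset))
        emit(accession)
        emit(". ")
    decoys = ["surplus", "XSRP12345", "SRP12345X", "SRR123", "the SRA archive", "PRJNA"]
    emit("Decoy context: the SRA archive itself, tokens like XSRP12345 and ")
    emit("SRP12345X inside words, a short SRR123, and a bare PRJNA mention. ")
    emit("Contact: curator@example.org.")
    return CorpusTruth(text="".join(parts), planted=planted, decoys=decoys)


def make_metadata(seed: int = 0) -> MetadataTruth:
    """Raw sample metadata covering every recognised date/coordinate
    dialect plus malformed cases, with per-row expected curated values."""
    del seed  # content is fixed; the signature keeps generators uniform
    rows = [
        # srs, date, country, lat_lon, habitat, material
        ("SRS000001", "12-Aug-2014", "Netherlands", "52°09′36″N 4°29′E",
         "temperate broadleaf forest soil", "soil"),
        ("SRS000002", "2014", "Brazil", None, "lowland rainforest soil", "soil"),
        ("SRS000003", "Aug-2014", "Netherlands", "-33.9, 151.2", None, None),
        ("SRS000004", "08/12/2014", "Australia", "25.27 S 133.78 E",
         "dry grassland soil sample", "soil"),
        ("SRS000005", "sometime in summer", "Atlantis", "95 N 10 E", "void", None),
        ("SRS000006", "2014-08-12", "usa", None, "SOIL", "bulk soil"),
    ]
    raw = pd.DataFrame(
        rows,
        columns=["srs", "collection_date", "geo_loc_name", "lat_lon",
                 "env_biome", "env_material"],
    )
    expected = pd.DataFrame(
        [
            ("SRS000001", "2014-08-12", "Netherlands", "Europe",
             round(52 + 9 / 60 + 36 / 3600, 6), round(4 + 29 / 60, 6),
             "REPORTED", "forest soil"),
            ("SRS000002", "2014", "Brazil", "South America",
             -14.2350, -51.9253, "CENTROID_FALLBACK", "forest soil"),
            ("SRS000003", "2014-08", "Netherlands", "Europe",
             52.1326, 5.2913, "CORRECTED", None),
            ("SRS000004", "2014-08-12", "Australia", "Oceania",
             -25.27, 133.78, "REPORTED", "grassland soil"),
            ("SRS000005", None, None, None, None, None, "REPORTED", None),
            ("SRS000006", "2014-08-12", "United States", "North America",
             39.7837, -100.4459, "CENTROID_FALLBACK", "soil"),
        ],
        columns=["srs", "expected_date", "expected_country", "expected_continent",
                 "expected_lat", "expected_lon", "expected_coord_source",
                 "expected_biome_label"],
    )
    return MetadataTruth(raw=raw, expected=expected)


def make_corpus_and_metadata(
    seed: int = 0, out_dir: Union[str, Path, None] = None
) -> tuple[CorpusTruth, MetadataTruth]:
    corpus = make_corpus(seed)
    metadata = make_metadata(seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "corpus.txt").write_text(corpus.text)
        pd.DataFrame(
            corpus.planted, columns=["accession", "prefix_class", "char_offset"]
        ).to_csv(out_dir / "corpus_truth.csv", index=False)
        metadata.raw.to_csv(out_dir / "samples_raw.csv", index=False)
        metadata.expected.to_csv(out_dir / "samples_expected.csv", index=False)
    return corpus, metadata
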