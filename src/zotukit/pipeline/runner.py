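"""End-to-end amplicon processing: FASTQ in, filtered ZOTU set out.

Illumina platforms run trim -> merge -> filter -> dereplicate ->
denoise -> taxonomy filter; single-read platforms (454, Ion Torrent)
skip the merge.  Every run emits a per-stage count report satisfying the
conservation law

    reads_in = trim_discarded + merge_failed + filtered_out
               + sum(ZOTU abundances) + denoise_rejected

(ZOTU abundances counted before the taxonomy filter) and a process
record capturing every parameter value used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .. import PIPELINE_VERSION
from .denoise import DenoiseParams, DenoiseResult, ZotuRecord, denoise, label_zotus
from .derep import dereplicate
from .merge import merge_pair
from .quality import quality_filter
from .reads import read_fastq, write_zotu_fasta
from .runner_report import conservation_holds  # re-exported helper
from .taxonomy import (
    ReferenceRecord,
    TaxonAssignment,
    load_reference_fasta,
    taxonomy_filter,
)
from .trim import trim_primers


class Platform(str, Enum):
    ILLUMINA_MISEQ = "ILLUMINA_MISEQ"
    ILLUMINA_HISEQ = "ILLUMINA_HISEQ"
    LS454_JUNIOR = "LS454_JUNIOR"
    LS454_FLX_TITANIUM = "LS454_FLX_TITANIUM"
    LS454_FLX_PLUS = "LS454_FLX_PLUS"
    ION_PGM = "ION_PGM"

    @property
    def paired(self) -> bool:
        return self in (Platform.ILLUMINA_MISEQ, Platform.ILLUMINA_HISEQ)


@dataclass
class PipelineParams:
    fwd_primer: str
    rev_primer: str
    marker: str  # ITS1 | ITS2
    platform: Platform
    max_ee: float = 1.0
    min_overlap: int = 60
    min_length: int = 250

    def __post_init__(self) -> None:
        if isinstance(self.platform, str) and not isinstance(self.platform, Platform):
            self.platform = Platform(self.platform)
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("both primers are mandatory")
        if self.marker not in ("ITS1", "ITS2"):
            raise ValueError("marker must be ITS1 or ITS2")
        if self.max_ee <= 0:
            raise ValueError("max_ee must be positive")
        if self.min_overlap < 1 or self.min_length < 1:
            raise ValueError("min_overlap and min_length must be >= 1")


@dataclass
class PipelineResult:
    zotus: list[ZotuRecord]  # taxonomy-filtered (or all, without reference)
    assignments: dict[str, TaxonAssignment]  # zotu_id -> assignment
    discarded_zotus: list[ZotuRecord]
    report: dict[str, int]
    process_record: dict[str, object]
    denoise_detail: DenoiseResult = field(repr=False, default=None)


def make_process_record(
    params: PipelineParams, denoise_params: DenoiseParams, srr: Optional[str] = None
) -> dict[str, object]:
    return {
        "srr": srr,
        "fwd_primer": params.fwd_primer,
        "rev_primer": params.rev_primer,
        "marker": params.marker,
        "platform": params.platform.value,
        "max_ee": params.max_ee,
        "min_overlap": params.min_overlap,
        "min_length": params.min_length,
        "alpha": denoise_params.alpha,
        "min_size": denoise_params.min_size,
        "identity_definition": (
            "matches/alignment-columns, global alignment with free end gaps"
        ),
        "pipeline_version": PIPELINE_VERSION,
    }


def run_pipeline(
    fwd_path: Union[str, Path],
    params: PipelineParams,
    rev_path: Union[str, Path, None] = None,
    reference: Union[str, Path, list[ReferenceRecord], None] = None,
    denoise_params: Optional[DenoiseParams] = None,
    srr: Optional[str] = None,
    out_dir: Union[str, Path, None] = None,
) -> PipelineResult:
    """Process one run's FASTQ file(s) into ZOTUs.

    Paired platforms require ``rev_path``; single-read platforms forbid
    it.  Both are checked before any processing.
    """
    denoise_params = denoise_params or DenoiseParams()
    if params.platform.paired and rev_path is None:
        raise ValueError(f"platform {params.platform.value} requires a mate file")
    if not params.platform.paired and rev_path is not None:
        raise ValueError(f"platform {params.platform.value} takes a single file")

    report: dict[str, int] = {
        "reads_in": 0,
        "trim_discarded": 0,
        "merge_failed": 0,
        "reads_filtered_out": 0,
        "reads_kept": 0,
        "uniques": 0,
        "zotus": 0,
        "denoise_rejected_reads": 0,
        "zotus_kept_taxonomy": 0,
        "zotus_discarded_taxonomy": 0,
    }

    prepared = []
    if params.platform.paired:
        fwd_reads = list(read_fastq(fwd_path))
        rev_reads = list(read_fastq(rev_path))
        if len(fwd_reads) != len(rev_reads):
            raise ValueError(
                f"mate files differ in read count: {len(fwd_reads)} vs {len(rev_reads)}"
            )
        report["reads_in"] = len(fwd_reads)
        for f, r in zip(fwd_reads, rev_reads):
            tf = trim_primers(f, params.fwd_primer, params.rev_primer)
            tr = trim_primers(r, params.rev_primer, params.fwd_primer)
            if tf is None or tr is None:
                report["trim_discarded"] += 1
                continue
            merged = merge_pair(tf, tr, min_overlap=params.min_overlap)
            if merged is None:
                report["merge_failed"] += 1
                continue
            prepared.append(merged)
    else:
        for read in read_fastq(fwd_path):
            report["reads_in"] += 1
            trimmed = trim_primers(read, params.fwd_primer, params.rev_primer)
            if trimmed is None:
                report["trim_discarded"] += 1
                continue
            prepared.append(trimmed)

    kept, filter_counts = quality_filter(prepared, params.max_ee, params.min_length)
    report["reads_filtered_out"] = filter_counts["reads_filtered_out"]
    report["reads_kept"] = len(kept)

    uniques = dereplicate(r.sequence for r in kept)
    report["uniques"] = len(uniques)

    denoised = denoise(uniques, denoise_params)
    report["denoise_rejected_reads"] = denoised.rejected_reads
    all_zotus = label_zotus(denoised, params.marker)
    report["zotus"] = len(all_zotus)

    assignments: dict[str, TaxonAssignment] = {}
    discarded: list[ZotuRecord] = []
    if reference is not None:
        refs = (
            reference
            if isinstance(reference, list)
            else load_reference_fasta(reference)
        )
        kept_pairs, discarded = taxonomy_filter(all_zotus, refs)
        zotus = [z for z, _ in kept_pairs]
        assignments = {z.zotu_id: a for z, a in kept_pairs}
    else:
        zotus = all_zotus
    report["zotus_kept_taxonomy"] = len(zotus) if reference is not None else 0
    report["zotus_discarded_taxonomy"] = len(discarded)

    process_record = make_process_record(params, denoise_params, srr=srr)
    result = PipelineResult(
        zotus=zotus,
        assignments=assignments,
        discarded_zotus=discarded,
        report=report,
        process_record=process_record,
        denoise_detail=denoised,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_zotu_fasta(zotus, out_dir / "zotus.fasta")
        with open(out_dir / "report.json", "w") as handle:
            json.dump(report, handle, indent=2)
        pd.DataFrame([process_record]).to_csv(out_dir / "process.csv", index=False)
    return result
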