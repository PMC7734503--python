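"""Stage-report helpers."""

from __future__ import annotations

from typing import Mapping, Sequence


def conservation_holds(report: Mapping[str, int], zotu_abundances: Sequence[int]) -> bool:
    """Check the read-conservation law of a pipeline stage report.

    Every input read (pair) ends up in exactly one bucket: primer-trim
    discard, merge failure, quality-filter rejection, a ZOTU's absorbed
    abundance, or a below-min-size unique that joined no centroid.
    """
    return report["reads_in"] == (
        report["trim_discarded"]
        + report["merge_failed"]
        + report["reads_filtered_out"]
        + sum(zotu_abundances)
        + report["denoise_rejected_reads"]
    )
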