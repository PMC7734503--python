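from __future__ import annotations

import numpy as np
import pytest

from zotukit.curation import load_envo_dictionary
from zotukit.gazetteer import load_gazetteer
from zotukit.pipeline.denoise import ZotuRecord
from zotukit.pipeline.taxonomy import Lineage, TaxonAssignment
from zotukit.primers import load_primer_table


@pytest.fixture(scope="session")
def gazetteer():
    return load_gazetteer()


@pytest.fixture(scope="session")
def envo_dict():
    return load_envo_dictionary()


@pytest.fixture(scope="session")
def primer_table():
    return load_primer_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_zotu(sequence: str, abundance: int = 10, marker: str = "ITS2") -> ZotuRecord:
    return ZotuRecord(
        zotu_id="Zotu0", sequence=sequence, abundance=abundance, marker=marker
    )


def make_assignment(
    phylum: str = "Basidiomycota",
    family: str = "Russulaceae",
    identity: float = 97.0,
    kingdom: str = "Fungi",
) -> TaxonAssignment:
    lineage = Lineage.from_string(
        f"k__{kingdom};p__{phylum};c__C;o__O;f__{family};g__G;s__G_sp"
    )
    return TaxonAssignment(lineage=lineage, best_hit_name="REF00000", identity=identity)
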