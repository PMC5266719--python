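import numpy as np
import pytest

from redoxquant.design import ChannelDesign
from redoxquant.peptides import parse_modified_sequence
from redoxquant.psm import PSMRecord, PSMSet


@pytest.fixture
def design():
    return ChannelDesign.default()


def make_record(annotated, accessions, replicate, iodo=None, itraq=None):
    peptide = parse_modified_sequence(annotated, accessions)
    if itraq is None:
        itraq = {label: 1000.0 for label in "113 114 115 116 117 118".split()}
    return PSMRecord(
        peptide=peptide,
        replicate=replicate,
        iodo_intensities=iodo or {},
        itraq_intensities=itraq,
    )


@pytest.fixture
def small_psmset(design):
    """Three replicates, two labeled Cys peptides on separate proteins."""
    rng = np.random.default_rng(7)
    records = []
    for replicate in design.replicates:
        for annotated, acc in [
            ("aVLcDEFGHK", "PROT1"),
            ("gHIcLMNPQR", "PROT2"),
            ("dQRSVWADEK", "PROT3"),  # no Cys: iTRAQ only
        ]:
            iodo = {
                label: float(rng.uniform(500, 2000))
                for label in "126 127 128 129 130 131".split()
            } if "c" in annotated else {}
            itraq = {
                label: float(rng.uniform(500, 2000))
                for label in "113 114 115 116 117 118".split()
            }
            records.append(make_record(annotated, [acc], replicate, iodo, itraq))
    return PSMSet(records=tuple(records), design=design)
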