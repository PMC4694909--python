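import numpy as np
import pytest

from sumscan.cna_core import CnaCategory, GeneCnaCall
from sumscan.io_formats import GeneAnnotation, SegmentRecord
from sumscan.target_scoring import TargetPanel, REGORAFENIB_TARGETS


@pytest.fixture
def rng():
    return np.random.default_rng(20150721)


@pytest.fixture
def regorafenib_panel():
    return TargetPanel(drug="regorafenib", genes=REGORAFENIB_TARGETS)


def make_call(gene, log2, sample="S1"):
    from sumscan.cna_core import categorize_log2

    return GeneCnaCall(
        sample_id=sample,
        gene_symbol=gene,
        category=categorize_log2(log2),
        log2_ratio=log2,
    )


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("KIT", "4", 54_000_000, 54_100_000),
        GeneAnnotation("BRAF", "7", 140_000_000, 140_200_000),
        GeneAnnotation("RET", "10", 43_000_000, 43_050_000),
    ]


@pytest.fixture
def toy_segments():
    return [
        SegmentRecord("S1", "4", 53_000_000, 55_000_000, 0.7),
        SegmentRecord("S1", "7", 139_000_000, 140_050_000, -1.2),
        SegmentRecord("S1", "7", 140_050_000, 141_000_000, 0.2),
    ]
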