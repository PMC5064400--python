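import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from bgcscan.io import ContigRecord, GeneAnnotation, GeneModel


@pytest.fixture
def ten_gene_annotation() -> GeneAnnotation:
    """A hand-built 10-gene annotation on two contigs with known statistics.

    Exon counts: [1, 2, 3, 1, 2, 1, 4, 1, 2, 3] -> 20 exons, 10 introns.
    Genes 2 and 3 on contigA overlap (spans 1001-2000 and 1501-2600).
    """
    g = []
    # contigA (length 10000)
    g.append(GeneModel("g01", "contigA", 101, 400, "+", ((101, 400),)))
    g.append(GeneModel("g02", "contigA", 1001, 2000, "+", ((1001, 1300), (1501, 2000))))
    g.append(GeneModel("g03", "contigA", 1501, 2600, "-", ((1501, 1700), (1801, 2100), (2301, 2600))))
    g.append(GeneModel("g04", "contigA", 3001, 3500, "+", ((3001, 3500),)))
    g.append(GeneModel("g05", "contigA", 5001, 6000, "-", ((5001, 5400), (5601, 6000))))
    # contigB (length 8000)
    g.append(GeneModel("g06", "contigB", 201, 700, "+", ((201, 700),)))
    g.append(GeneModel("g07", "contigB", 1001, 2200, "+", ((1001, 1200), (1301, 1500), (1601, 1800), (1901, 2200))))
    g.append(GeneModel("g08", "contigB", 3001, 3300, "-", ((3001, 3300),)))
    g.append(GeneModel("g09", "contigB", 4001, 4800, "+", ((4001, 4300), (4501, 4800))))
    g.append(GeneModel("g10", "contigB", 6001, 7200, "-", ((6001, 6300), (6501, 6800), (7001, 7200))))
    return GeneAnnotation(g)


@pytest.fixture
def two_contigs() -> list[ContigRecord]:
    return [
        ContigRecord("contigA", 10_000),
        ContigRecord("contigB", 8_000),
    ]
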