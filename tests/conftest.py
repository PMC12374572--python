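import pytest

from clonalarch.io import (
    LocusGenotype,
    MarkerPanel,
    QuadratLayout,
    RametRecord,
    SampleSet,
    Stage,
)


def make_record(sample_id, row, col, alleles, quadrat="Q1", stage=Stage.ON_FLOOR):
    """alleles: sequence of (a, b) pairs, one per locus."""
    return RametRecord(
        sample_id, quadrat, row, col, stage,
        tuple(LocusGenotype(a, b) for a, b in alleles),
    )


def make_sample_set(allele_rows, quadrat="Q1", rows=10, cols=10):
    """Build a SampleSet from a list of per-sample allele-pair lists.

    Samples are named S1, S2, ... and placed on distinct grid cells in order.
    """
    n_loci = len(allele_rows[0])
    panel = MarkerPanel(tuple(f"L{i+1:02d}" for i in range(n_loci)))
    records = []
    for i, alleles in enumerate(allele_rows):
        r, c = divmod(i, cols)
        records.append(make_record(f"S{i+1}", r + 1, c + 1, alleles, quadrat))
    layout = QuadratLayout(quadrat, grid_rows=rows, grid_cols=cols)
    return SampleSet(panel, {quadrat: layout}, records)


@pytest.fixture
def two_locus_trio():
    """Three samples at 2 loci: A=(100/100, 200/200), B=(100/100, 200/202),
    C=(102/104, 200/200)."""
    return make_sample_set([
        [(100, 100), (200, 200)],
        [(100, 100), (200, 202)],
        [(102, 104), (200, 200)],
    ])
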