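import pytest

from nbscreen import (
    AmpliconCoverage,
    AmpliconRecord,
    AssayKind,
    BiochemicalResult,
    Classification,
    Marker,
    VariantCall,
    Zygosity,
    default_cutoffs,
)
from nbscreen.cnv import EXON17_TARGET


@pytest.fixture(scope="session")
def cutoffs():
    return default_cutoffs()


def make_result(sample_id="S1", assay=AssayKind.MASSCHROM, **markers):
    """Build a BiochemicalResult from keyword marker values, e.g. CIT=27."""
    values = {Marker[name]: value for name, value in markers.items()}
    return BiochemicalResult(sample_id=sample_id, assay=assay, values=values)


def make_variant(gene, zygosity=Zygosity.HET, classification=Classification.P,
                 sample_id="S1", hgvs="c.1A>G"):
    return VariantCall(
        sample_id=sample_id,
        gene=gene,
        hgvs=hgvs,
        zygosity=zygosity,
        classification=classification,
    )


def make_coverage(depths, sample_id="S1", ex17_index=None):
    """Coverage with given depths; the last amplicon is exon 17 unless
    ``ex17_index`` says otherwise."""
    if ex17_index is None:
        ex17_index = len(depths) - 1
    records = []
    for i, depth in enumerate(depths):
        target = EXON17_TARGET if i == ex17_index else f"SLC25A13_other{i}"
        records.append(
            AmpliconRecord(
                amplicon_id=f"amp{i:02d}",
                gene="SLC25A13",
                target=target,
                depth=int(depth),
            )
        )
    return AmpliconCoverage(sample_id=sample_id, records=tuple(records))
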