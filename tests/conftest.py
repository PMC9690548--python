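import numpy as np
import pandas as pd
import pytest

from culicinet.io_formats import CountTable, TaxonomyMap, SampleMetadata, parse_lineage
from culicinet.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def tiny_table():
    data = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 5], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    return CountTable(data)


@pytest.fixture
def tiny_taxonomy():
    return TaxonomyMap({
        "ASV1": parse_lineage("d__Bacteria; p__Proteobacteria; c__Alpha; "
                              "o__Rhodospirillales; f__Acetobacteraceae; g__Asaia"),
        "ASV2": parse_lineage("d__Bacteria; p__Proteobacteria; c__Alpha; "
                              "o__Rhodospirillales; f__Acetobacteraceae; g__Asaia"),
        "ASV3": parse_lineage("d__Bacteria; p__Actinobacteriota; c__Actinobacteria; "
                              "o__Pseudonocardiales; f__Pseudonocardiaceae"),
        "ASV4": parse_lineage("d__Bacteria; p__Proteobacteria; c__Alpha; "
                              "o__Rickettsiales; f__Anaplasmataceae; g__Wolbachia"),
    })


@pytest.fixture
def tiny_metadata():
    return SampleMetadata({"s1": "spA", "s2": "spA", "s3": "spB"})


def small_spec(seed=7, **kw):
    """Scaled-down synthetic design for fast module/integration tests."""
    defaults = dict(
        species={"spA": 8, "spB": 6, "spC": 30},
        n_taxa=60,
        depth_range=(2000, 5000),
        shared_genus_pairs=4,
        differential={"spA": [(12, 100.0)]},
        seed=seed,
    )
    defaults.update(kw)
    defaults["differential"] = {
        sp: v for sp, v in defaults["differential"].items()
        if sp in defaults["species"]
    }
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(small_spec())
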