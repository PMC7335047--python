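import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from benthoscan.catalog import GeneCatalog


def make_catalog(spec):
    """Build a GeneCatalog from a compact spec: {scaffold: [family, ...]}
    where the list index is the rank and None means no family."""
    records = []
    for scaffold, families in spec.items():
        for rank, family in enumerate(families):
            start = 1000 * rank + 1
            records.append(dict(
                gene_id=f"{scaffold}.{rank}", scaffold=scaffold, rank=rank,
                strand="+", family=family,
                exons=((start, start + 299),),
            ))
    return GeneCatalog(pd.DataFrame.from_records(records))


@pytest.fixture
def toy_catalog():
    return make_catalog({"s1": ["A", "A", "B", None, "B", "C"],
                         "s2": ["C", "D", "D"]})
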