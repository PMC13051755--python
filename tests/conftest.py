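import numpy as np
import pandas as pd
import pytest

from phyllokbs.io_core import CountTable, SampleMetadata, Taxonomy


@pytest.fixture
def small_table() -> CountTable:
    """5 taxa x 3 samples with hand-checkable entries."""
    counts = np.array(
        [
            [5, 0, 2],
            [0, 0, 0],
            [1, 1, 1],
            [0, 4, 0],
            [3, 2, 0],
        ]
    )
    return CountTable(counts, [f"t{i}" for i in range(5)], ["s1", "s2", "s3"])


@pytest.fixture
def random_table() -> CountTable:
    rng = np.random.default_rng(42)
    counts = rng.poisson(5.0, size=(20, 10))
    counts[0, :] += 1  # ensure a taxon present everywhere
    return CountTable(counts, [f"t{i}" for i in range(20)], [f"s{j}" for j in range(10)])


def make_metadata(sample_ids, resistance, yields=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    soil = rng.normal([6.5, 15, 20, 200, 10, 20], [0.3, 5, 5, 50, 3, 6], size=(n, 6))
    df = pd.DataFrame(
        {
            "cultivar": [f"cv{i % 5}" for i in range(n)],
            "resistance": resistance,
            "fertilization": ["control" if i % 2 else "fertilized" for i in range(n)],
            "replicate": [1 + i % 3 for i in range(n)],
            "yield": yields if yields is not None else rng.uniform(5, 10, n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for k, name in enumerate(("pH", "AP", "moisture", "DOC", "NH4_N", "NO3_N")):
        df[name] = soil[:, k]
    return SampleMetadata(df)


def make_taxonomy(taxon_ids, genera=None):
    rows = []
    for i, t in enumerate(taxon_ids):
        rows.append(
            {
                "taxon_id": t,
                "domain": "Bacteria",
                "phylum": "Proteobacteria",
                "class": "Alphaproteobacteria",
                "order": "o1",
                "family": "f1",
                "genus": genera[i] if genera else f"Genus{i}",
                "species": "",
            }
        )
    return Taxonomy(pd.DataFrame(rows).set_index("taxon_id"))
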