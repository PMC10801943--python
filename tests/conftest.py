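import numpy as np
import pandas as pd
import pytest

from coreniche.table import AbundanceTable, SampleMetadata, TaxonomyTable, RANKS


@pytest.fixture
def tiny_table():
    counts = np.array([[6, 2, 0], [2, 2, 1]])
    return AbundanceTable(counts, ["s1", "s2"], ["t1", "t2", "t3"])


@pytest.fixture
def grouped_table():
    # 8 samples, 2 groups of 4; taxon layout exercised by occupancy tests
    counts = np.array(
        [
            [5, 3, 0, 1],
            [4, 0, 0, 1],
            [6, 2, 0, 1],
            [5, 0, 0, 1],
            [3, 0, 1, 1],
            [4, 0, 2, 1],
            [5, 0, 1, 1],
            [6, 0, 3, 1],
        ]
    )
    samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    return AbundanceTable(counts, samples, ["t1", "t2", "t3", "t4"])


@pytest.fixture
def grouped_metadata(grouped_table):
    df = pd.DataFrame(
        {"site": ["A"] * 4 + ["B"] * 4},
        index=pd.Index(grouped_table.sample_ids, name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture
def taxonomy4():
    rows = {
        "t1": ["Bacteria", "Firmicutes", "Clostridia", "Oscillospirales",
               "Ruminococcaceae", "Faecalibacterium", ""],
        "t2": ["Bacteria", "Proteobacteria", "Alphaproteobacteria",
               "Rickettsiales", "Mitochondria", "", ""],
        "t3": ["Bacteria", "Cyanobacteria", "", "Chloroplast", "", "", ""],
        "t4": ["", "", "", "", "", "", ""],
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "taxon_id"
    return TaxonomyTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_samples=5, n_taxa=8, max_count=30, min_depth=1):
    """Random small AbundanceTable guaranteeing positive sample depths."""
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    for i in range(n_samples):
        if counts[i].sum() < min_depth:
            counts[i, rng.integers(n_taxa)] += min_depth
    return AbundanceTable(
        counts, [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_taxa)],
    )
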