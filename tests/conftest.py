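import numpy as np
import pandas as pd
import pytest

from sigassoc.containers import AlterationMatrix


@pytest.fixture
def toy_catalog() -> pd.DataFrame:
    """Hand-countable mutation catalog.

    s1: nonsilent in g1, g2 + silent in g3; s2: nonsilent g1, g2;
    s3: nonsilent g1; s4: nonsilent g1; g3 silent-only everywhere.
    """
    rows = [
        ("s1", "g1", "nonsilent"),
        ("s1", "g2", "nonsilent"),
        ("s1", "g3", "silent"),
        ("s2", "g1", "nonsilent"),
        ("s2", "g2", "nonsilent"),
        ("s3", "g1", "nonsilent"),
        ("s4", "g1", "nonsilent"),
        ("s4", "g3", "silent"),
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])


@pytest.fixture
def toy_segments() -> pd.DataFrame:
    """Segments on one chromosome: s1/s2 amplified, s3 deleted, s4 neutral."""
    rows = [
        ("s1", "1", 100, 199, 0.6),
        ("s2", "1", 100, 199, 0.8),
        ("s3", "1", 100, 199, -0.7),
        ("s4", "1", 100, 199, 0.3),
        ("s1", "1", 200, 299, 0.9),
        ("s2", "1", 200, 299, 0.7),
        ("s3", "1", 200, 299, 0.55),
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_mean"])


def make_matrix(rows: dict, samples, kind="mutation", regions=None) -> AlterationMatrix:
    data = pd.DataFrame(rows, index=samples).T.astype(np.int8)
    return AlterationMatrix(data, kind, regions)
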