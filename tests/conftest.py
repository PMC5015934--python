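import numpy as np
import pandas as pd
import pytest

from demeth.io import CONTEXTS, classify_context

METH_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "total", "call"]


def build_meth(rows):
    """Build an in-memory cytosine table from (chrom, pos, strand, context,
    mc, total, call) tuples, deriving the context class."""
    df = pd.DataFrame(rows, columns=METH_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["mc"] = df["mc"].astype(np.int64)
    df["total"] = df["total"].astype(np.int64)
    df["call"] = df["call"].astype(np.int64)
    df["context_class"] = pd.Categorical(
        [classify_context(c) for c in df["context"]], categories=list(CONTEXTS))
    return df


def random_meth(rng, n=200, chroms=("chr1",), max_pos=10_000, max_cov=40):
    """A random cytosine table for oracle-equivalence checks."""
    contexts = ["CGA", "CGT", "CAG", "CTG", "CAA", "CTT", "CCA"]
    total = rng.integers(0, max_cov + 1, n)
    mc = rng.binomial(total, rng.random(n))
    rows = [
        (rng.choice(chroms), int(p), rng.choice(["+", "-"]),
         contexts[rng.integers(len(contexts))], int(m), int(t),
         int(rng.integers(0, 2)))
        for p, m, t in zip(rng.integers(1, max_pos + 1, n), mc, total)
    ]
    df = build_meth(rows)
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@pytest.fixture
def meth_frame():
    return build_meth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
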