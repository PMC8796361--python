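import numpy as np
import pandas as pd
import pytest

from subspec.snv_core import SNVTable


def make_snv_table(ref_count, alt_count, coverage=None, species="sp",
                   sample_ids=None):
    """Small SNVTable from plain nested lists (rows = SNVs)."""
    ref_count = np.asarray(ref_count, dtype=np.int64)
    alt_count = np.asarray(alt_count, dtype=np.int64)
    coverage = (
        ref_count + alt_count if coverage is None
        else np.asarray(coverage, dtype=np.int64)
    )
    n, s = ref_count.shape
    snvs = pd.DataFrame(
        {
            "contig": "c1",
            "pos": np.arange(1, n + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(s)]
    return SNVTable(species, snvs, ref_count, alt_count, coverage, sample_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_freq_matrix(rng, n_snvs=30, n_samples=8, missing_rate=0.2):
    vals = rng.random((n_snvs, n_samples))
    vals[rng.random(vals.shape) < missing_rate] = np.nan
    return pd.DataFrame(
        vals,
        index=[f"c1:{i + 1}:A>T" for i in range(n_snvs)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
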