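import numpy as np
import pandas as pd
import pytest

from clonemap import cna, fixtures

SUBCLONES = ("s1", "s2", "s3")


def make_cna_dataset(seed: int, n_bins: int = 200, reads: int = 100_000,
                     n_samples: int = 9):
    """Reference + tumor samples from 3 planted subclones, with GC bias."""
    bins = fixtures.uniform_bins(fixtures.default_genome(), n_bins)
    profiles, events = fixtures.make_subclone_profiles(bins, list(SUBCLONES),
                                                       seed=seed)
    profiles["ref"] = np.full(n_bins, 2)
    samples = [(f"c{i}", SUBCLONES[i % 3]) for i in range(n_samples)]
    counts = fixtures.simulate_binned_depth(
        bins, profiles, [("ref", "ref"), *samples], reads_per_sample=reads,
        gc_bias=fixtures.quadratic_gc_bias, seed=seed,
    )
    return bins, counts, samples, events


def copy_number_matrix(bins, counts) -> pd.DataFrame:
    ref = counts["ref"].to_numpy()
    cn = {
        col: cna.assign_and_normalize(col, counts[col].to_numpy(), bins, ref).copy_number
        for col in counts.columns
    }
    return pd.DataFrame(cn, index=counts.index)


@pytest.fixture(scope="session")
def demo_mask():
    return fixtures.make_mask_with_groups(3, 8, (512, 512), seed=7)


@pytest.fixture(scope="session")
def cna_dataset():
    return make_cna_dataset(seed=11)
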