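import pandas as pd
import pytest

import kdrcost as k


@pytest.fixture(scope="session")
def kr_series():
    """The four cage series of the kdr-only (KR x ROCK) competition experiment."""
    return k.read_genotype_table(k.fixture_path("kr_table2.csv"))


@pytest.fixture(scope="session")
def ckr_series():
    """The four cage series of the kdr+CYP (CKR x ROCK) competition experiment."""
    return k.read_genotype_table(k.fixture_path("ckr_table3.csv"))


@pytest.fixture(scope="session")
def published_stats():
    """Published per-row report cells (frequencies, HWE p, drift p) with reconstruction flags."""
    return pd.read_csv(k.fixture_path("published_reversion_stats.csv"))


def by_cage_gen(series_list, cage_id, generation):
    for s in series_list:
        if s.cage_id == cage_id:
            for c in s:
                if c.generation == generation:
                    return c
    raise KeyError((cage_id, generation))
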