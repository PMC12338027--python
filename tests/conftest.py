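import copy

import numpy as np
import pandas as pd
import pytest

import cfpipe


@pytest.fixture(scope="session")
def small_genome():
    """1 x 10 Mb genome with a modest TFBS catalog; shared read-only."""
    return cfpipe.make_reference(
        n_chrom=1,
        chrom_length=10_000_000,
        gc_window=50_000,
        n_tfs=2,
        sites_per_tf=60,
        seed=7,
        blacklist_fraction=0.02,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Default config scaled down for fast end-to-end tests."""
    cfg = copy.deepcopy(cfpipe.load_default_config())
    for c in cfg["cohorts"].values():
        c["n_subjects"] = 10
        c["fragments_per_subject"] = 3000
    cfg["genome"]["sites_per_tf"] = 80
    cfg["cnv"]["n_reference"] = 3
    return cfg


def make_frags(chrom, starts, ends, mapq=60, strand="+", motif="ACGT", duplicate=False):
    """Hand-built fragment frame for unit tests."""
    n = len(starts)

    def expand(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "chrom": expand(chrom),
            "start": list(starts),
            "end": list(ends),
            "name": [f"f{i}" for i in range(n)],
            "mapq": expand(mapq),
            "strand": expand(strand),
            "motif4": expand(motif),
            "duplicate": expand(duplicate),
        },
        columns=cfpipe.FRAGMENT_COLUMNS,
    )
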