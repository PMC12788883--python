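import numpy as np
import pandas as pd
import pytest

from adatpipe.decoding import (
    build_decoding_table,
    default_edited_families,
    default_families,
)
from adatpipe.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def full_table():
    """Decoding table over the full human isoacceptor set."""
    return build_decoding_table(default_families())


@pytest.fixture(scope="session")
def edited_table():
    """Decoding table over only the 8 ADAT-edited families."""
    return build_decoding_table(default_edited_families())


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small end-to-end synthetic bundle written to disk once per session."""
    cfg = SimConfig(
        seed=7,
        coverage=400,
        n_genes=300,
        orf_length_range=(60, 120),
        depth=3e5,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    bundle = simulate_all(cfg, outdir)
    bundle["cfg"] = cfg
    bundle["outdir"] = outdir
    return bundle


def make_reads(rows):
    """Alignment-table helper: rows of (family, start, end, seq, mm, nh,
    leader, trailer, intron)."""
    cols = [
        "family_id",
        "start",
        "end",
        "seq",
        "mismatches",
        "n_mappings",
        "leader",
        "trailer",
        "intron",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "read_id", [f"r{i}" for i in range(len(df))])
    return df
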