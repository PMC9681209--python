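import numpy as np
import pandas as pd
import pytest

from hypobias.signatures import default_acs, opc_signatures


@pytest.fixture(scope="session")
def acs():
    return default_acs()


@pytest.fixture(scope="session")
def opc_sigs():
    return opc_signatures()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_manifest(positions, chrom="chr1"):
    """Manifest from explicit positions (one chromosome unless given pairs)."""
    rows = []
    for i, p in enumerate(positions):
        if isinstance(p, tuple):
            rows.append((f"cg{i:05d}", p[0], p[1]))
        else:
            rows.append((f"cg{i:05d}", chrom, int(p)))
    man = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]).set_index("probe_id")
    man["strand"] = "+"
    return man


def beta_frame(values, columns):
    """probes x samples beta DataFrame with cg-style index."""
    arr = np.asarray(values, dtype=float)
    index = [f"cg{i:05d}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=columns)
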