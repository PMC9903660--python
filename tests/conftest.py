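import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bins(n_bins: int, chrom: str = "1", gc=None, cutsites=5000,
              seed: int = 0) -> pd.DataFrame:
    """Uniform 500-kb bin metadata for synthetic matrices."""
    rng = np.random.default_rng(seed)
    if gc is None:
        gc = np.clip(0.42 + 0.08 * rng.standard_normal(n_bins), 0.25, 0.65)
    return pd.DataFrame({
        "chrom": [chrom] * n_bins,
        "start": np.arange(n_bins) * 500_000,
        "end": (np.arange(n_bins) + 1) * 500_000,
        "gc": np.broadcast_to(np.asarray(gc, dtype=float), (n_bins,)),
        "cutsites": np.broadcast_to(np.asarray(cutsites), (n_bins,)),
    })
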