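import numpy as np
import pandas as pd
import pytest

import provisio as pv


@pytest.fixture(scope="session")
def small_dataset():
    """One small two-tissue dataset with planted modules and DE effects."""
    design = pv.DesignSpec(n_genes=1000)
    counts, meta, truth = pv.generate_counts(design, seed=11)
    return counts, meta, truth


@pytest.fixture(scope="session")
def oocyte_logcpm(small_dataset):
    counts, meta, _ = small_dataset
    m = meta[meta["tissue"] == "oocyte"]
    c = counts[m.index]
    factors = pv.tmm_factors(c)
    return pv.log_cpm(c, factors), m


@pytest.fixture()
def toy_counts():
    """Tiny deterministic count matrix (4 features x 3 samples)."""
    return pd.DataFrame(
        {
            "s1": [100, 200, 0, 700],
            "s2": [110, 190, 5, 695],
            "s3": [90, 210, 2, 698],
        },
        index=[f"f{i}" for i in range(4)],
    )


def block_expression(sizes, n_samples=22, noise_sd=0.3, seed=0, n_background=0):
    """Expression with perfectly block-structured latent factors (samples x genes)."""
    rng = np.random.default_rng(seed)
    cols, data = [], []
    for b, size in enumerate(sizes, start=1):
        f = rng.standard_normal(n_samples)
        for j in range(size):
            cols.append(f"b{b}_g{j}")
            data.append(f + noise_sd * rng.standard_normal(n_samples))
    for j in range(n_background):
        cols.append(f"bg_g{j}")
        data.append(rng.standard_normal(n_samples))
    expr = pd.DataFrame(np.array(data).T, columns=cols,
                        index=[f"s{i}" for i in range(n_samples)])
    truth = pd.Series(
        [b for b, size in enumerate(sizes, start=1) for _ in range(size)]
        + [0] * n_background,
        index=cols,
    )
    return expr, truth
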