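import numpy as np
import pandas as pd
import pytest

from autoreg.simulate import (SimConfig, generate_annotation, generate_peak_counts,
                              generate_timecourse_counts)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=300, n_autophagy=30, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One small simulated scenario shared by read-only tests."""
    counts, samples, truth = generate_timecourse_counts(small_cfg)
    ann = generate_annotation(small_cfg.n_genes, seed=small_cfg.seed)
    peaks, peak_counts, truth, chip_samples = generate_peak_counts(
        small_cfg, ann, truth)
    return {
        "cfg": small_cfg, "counts": counts, "samples": samples, "truth": truth,
        "ann": ann, "peaks": peaks, "peak_counts": peak_counts,
        "chip_samples": chip_samples,
    }


@pytest.fixture()
def two_group_counts():
    """Deterministic NB counts with one planted log2FC=2 gene (B vs A)."""
    rng = np.random.default_rng(42)
    n, spg, alpha = 200, 8, 0.1
    base = 100 * 2.0 ** rng.normal(0, 1, n)
    lfc = np.zeros(n)
    lfc[0] = 2.0
    in_b = np.r_[np.zeros(spg), np.ones(spg)]
    mu = base[:, None] * 2.0 ** (lfc[:, None] * in_b[None, :])
    size = 1 / alpha
    counts = rng.negative_binomial(size, size / (size + mu))
    cm = pd.DataFrame(counts, index=[f"g{i:03d}" for i in range(n)],
                      columns=[f"s{j:02d}" for j in range(2 * spg)])
    groups = pd.Series(["A"] * spg + ["B"] * spg, index=cm.columns)
    return cm, groups
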