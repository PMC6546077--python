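import numpy as np
import pytest

from longqtl import CrossType, QTLSpec, SimulationConfig, simulate_dataset, uniform_map

TIMES11 = np.arange(1.0, 12.0)


def make_bc_config(
    n=60,
    seed=1,
    qtl_params=((30, 5, 0.5), (25, 5, 0.5)),
    n_chrom=2,
    n_markers=4,
    spacing=10.0,
    qtl_chrom="c1",
    qtl_pos=15.0,
    cov="AR1",
    cov_theta=(1.0, 0.6),
    times=TIMES11,
    **kw,
):
    return SimulationConfig(
        cross=CrossType.from_name("BC"),
        gmap=uniform_map(n_chrom, n_markers, spacing),
        qtl=QTLSpec(qtl_chrom, qtl_pos, np.array(qtl_params, dtype=float)),
        curve="logistic",
        cov=cov,
        cov_theta=np.array(cov_theta, dtype=float),
        times=np.asarray(times, dtype=float),
        n=n,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def bc_dataset():
    """Small BC dataset with a strong QTL at c1:15."""
    ds, truth = simulate_dataset(make_bc_config())
    return ds, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Same design but identical curves for both genotypes (no QTL)."""
    ds, truth = simulate_dataset(make_bc_config(qtl_params=((30, 5, 0.5), (30, 5, 0.5)), seed=2))
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
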