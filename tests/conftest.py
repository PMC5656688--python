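import numpy as np
import pytest

from foldedcca import PenaltySpec, generate_dataset, preset_designs
from foldedcca.simulate import SimulationDesign, make_block_signals

# one spec per family with its documented default gamma
ALL_SPECS = [
    PenaltySpec("l1"),
    PenaltySpec("lgamma"),
    PenaltySpec("geman"),
    PenaltySpec("scad"),
    PenaltySpec("laplace"),
    PenaltySpec("mcp"),
    PenaltySpec("etp"),
    PenaltySpec("log"),
]


@pytest.fixture(scope="session")
def design1_dataset():
    """One draw of the strong-signal (250, 600) study design."""
    return generate_dataset(preset_designs(seed=11)[0])


def small_design(seed=0, signal_scale=3.0, n=50, p=30, q=40):
    tu, tv = make_block_signals(p, q, n_blocks=2, block_width=4, seed=seed)
    return SimulationDesign(
        n=n, p=p, q=q, true_u=tu, true_v=tv,
        signal_scale=signal_scale, seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small strong-signal dataset for fast solver tests."""
    return generate_dataset(small_design(seed=3))


@pytest.fixture(scope="session")
def random_dataset():
    """A well-conditioned unstructured problem (i.i.d. Gaussian views).

    The exponential-kernel generator duplicates noise across equal-loading
    features, which makes saturating penalties unidentifiable along the
    duplicated directions; solver-level structural checks therefore use
    independent columns.
    """
    from foldedcca import Dataset

    rng = np.random.default_rng(2024)
    return Dataset(
        X=rng.standard_normal((40, 15)), Y=rng.standard_normal((40, 20))
    )


@pytest.fixture(scope="session")
def spiked_dataset():
    """Well-conditioned two-view data with a strong shared factor, sized so
    converged loading magnitudes exceed the folded-concave clipping points."""
    from foldedcca import Dataset

    rng = np.random.default_rng(77)
    n, p, q, k = 200, 10, 12, 3
    z = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    X[:, :k] += 3.0 * z[:, None]
    Y[:, :k] += 3.0 * z[:, None]
    return Dataset(X=X, Y=Y)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
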