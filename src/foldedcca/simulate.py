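"""Latent-variable synthetic data generator for two-view association studies.

Each subject i carries a scalar latent factor z_i ~ N(0, 1).  Given sparse
ground-truth loading vectors u (length p) and v (length q), the observed
rows are

    x_i ~ N(z_i · s · u, Σx),      y_i ~ N(z_i · s · v, Σy),

where s is a signal-strength multiplier and the noise covariances follow
the exponential kernel (Σx)_jk = exp(−|u_j − u_k|) (and symmetrically for
Σy): features with similar true loadings receive strongly correlated
noise, so the null features form a correlated background rather than
independent noise.  The true loadings are piecewise-constant with a few
contiguous nonzero blocks, and feature counts exceed the sample size
(the large-(p+q)-small-n regime in which plain CCA is ill-posed).

Four preset designs are provided: three at (p, q) = (250, 600) with
different signal strengths (hence different population canonical
correlations), and one at (p, q) = (500, 900).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .solver import Dataset

__all__ = [
    "SimulationDesign",
    "make_block_signals",
    "generate_dataset",
    "preset_designs",
]

#: Default sample size for the presets; any n below the feature counts
#: preserves the large-(p+q)-small-n regime.
DEFAULT_N = 100

#: Signal-strength multipliers for the four presets.  Design 2 is weakest
#: (hardest support recovery), designs 1 and 4 strongest.
PRESET_SCALES = (3.0, 0.8, 1.5, 3.0)


@dataclass(frozen=True)
class SimulationDesign:
    """Fully specified generating configuration for one synthetic dataset."""

    n: int
    p: int
    q: int
    true_u: np.ndarray
    true_v: np.ndarray
    signal_scale: float = 1.0
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_u", np.asarray(self.true_u, dtype=float))
        object.__setattr__(self, "true_v", np.asarray(self.true_v, dtype=float))
        if self.n < 1 or self.p < 1 or self.q < 1:
            raise ValueError("n, p, q must be positive")
        if self.true_u.shape != (self.p,) or self.true_v.shape != (self.q,):
            raise ValueError("true_u / true_v lengths must match p / q")
        for name, w in (("true_u", self.true_u), ("true_v", self.true_v)):
            nnz = int(np.count_nonzero(w))
            if nnz == 0:
                raise ValueError(f"{name} must have at least one nonzero entry")
            if nnz >= w.size:
                raise ValueError(f"{name} must be sparse (some zero entries)")
        if self.n >= self.p + self.q:
            raise ValueError(
                "design must satisfy n < p + q (more features than observations)"
            )
        if not (np.isfinite(self.signal_scale) and self.signal_scale >= 0):
            raise ValueError("signal_scale must be a finite nonnegative real")

    def with_seed(self, seed: int) -> "SimulationDesign":
        """Same design, different random seed (for replicates)."""
        return replace(self, seed=seed)

    def with_signal_scale(self, signal_scale: float) -> "SimulationDesign":
        return replace(self, signal_scale=signal_scale)


def make_block_signals(
    p: int,
    q: int,
    n_blocks: int = 3,
    block_width: int = 10,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant sparse truth vectors with contiguous nonzero blocks.

    Each vector is split into ``n_blocks`` equal segments and one block of
    ``block_width`` consecutive entries at height ``amplitude`` is placed
    uniformly at random inside each segment, so blocks never overlap.
    Deterministic given ``seed``.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive (a zero signal is not a signal)")
    if n_blocks < 1 or block_width < 1:
        raise ValueError("n_blocks and block_width must be positive")
    rng = np.random.default_rng(seed)

    def place(length: int) -> np.ndarray:
        seg = length // n_blocks
        if block_width > seg:
            raise ValueError(
                f"{n_blocks} blocks of width {block_width} do not fit in "
                f"length {length} without overlap"
            )
        w = np.zeros(length)
        for b in range(n_blocks):
            start = b * seg + rng.integers(0, seg - block_width + 1)
            w[start : start + block_width] = amplitude
        return w

    return place(p), place(q)


def _exp_kernel(w: np.ndarray) -> np.ndarray:
    """(Σ)_jk = exp(−|w_j − w_k|); unit diagonal by construction."""
    return np.exp(-np.abs(w[:, None] - w[None, :]))


def _cholesky_with_jitter(K: np.ndarray) -> np.ndarray:
    """Cholesky factor of K, adding diagonal jitter if K is only PSD
    (repeated loading values duplicate kernel rows exactly)."""
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(
                K if jitter == 0.0 else K + jitter * np.eye(K.shape[0])
            )
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance factorization failed even with jitter")


def generate_dataset(design: SimulationDesign) -> Dataset:
    """Draw one dataset from the latent-variable model; reproducible from seed."""
    rng = np.random.default_rng(design.seed)
    z = rng.standard_normal(design.n)

    def draw_view(w: np.ndarray, dim: int) -> np.ndarray:
        L = _cholesky_with_jitter(_exp_kernel(w))
        noise = rng.standard_normal((design.n, dim)) @ L.T
        return design.signal_scale * np.outer(z, w) + noise

    X = draw_view(design.true_u, design.p)
    Y = draw_view(design.true_v, design.q)
    return Dataset(
        X=X,
        Y=Y,
        true_u=design.true_u.copy(),
        true_v=design.true_v.copy(),
        row_ids=[f"s{i}" for i in range(design.n)],
        x_names=[f"x{j}" for j in range(design.p)],
        y_names=[f"y{j}" for j in range(design.q)],
    )


def preset_designs(n: int = DEFAULT_N, seed: int = 0) -> list[SimulationDesign]:
    """The four study designs: 1–3 at (250, 600) with distinct signal
    strengths, 4 at (500, 900).  ``seed`` controls the data draw; the block
    layout is fixed per design."""
    shapes = [(250, 600), (250, 600), (250, 600), (500, 900)]
    designs = []
    for i, ((p, q), scale) in enumerate(zip(shapes, PRESET_SCALES), start=1):
        tu, tv = make_block_signals(p, q, n_blocks=3, block_width=10, seed=i)
        designs.append(
            SimulationDesign(
                n=n,
                p=p,
                q=q,
                true_u=tu,
                true_v=tv,
                signal_scale=scale,
                seed=seed,
                name=f"design{i}",
            )
        )
    return designs
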