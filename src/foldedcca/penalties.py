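"""Folded-concave penalty functions, their supergradients, and LQA reweighting.

Eight penalty families are supported: the :math:`\\ell_1` norm (the convex
baseline) and seven non-convex, folded-concave penalties — the
:math:`\\ell_\\gamma` bridge norm (0 < γ < 1), Geman, SCAD, Laplace, MCP,
the exponential-type penalty (ETP) and the logarithm penalty.  Each is
parameterised by a sparsity weight ``lam`` (λ ≥ 0) and a concavity
parameter ``gamma`` (γ), is zero at the origin, singular at the origin
(which induces sparsity), and concave and non-decreasing on [0, ∞), so
large coefficients are penalised little or not at all.

The supergradient P′(t) — any slope of a line touching the concave
function from above — is non-increasing on [0, ∞) and drives the local
quadratic approximation (LQA): around an expansion point ``w_t`` the
penalty P(|w|) is majorized by ``P′(|w_t|)/(2|w_t|) · w² + C``, which
turns each penalized subproblem into a ridge-type linear system with
diagonal weights ``P′(|w_t|)/|w_t|``, perturbed by a tiny ζ so the
weights stay finite at zero coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "FAMILIES",
    "DEFAULT_GAMMA",
    "WEIGHT_FLOOR",
    "PenaltySpec",
    "penalty_value",
    "supergradient",
    "penalty_sum",
    "lqa_diag_weights",
]

FAMILIES = ("l1", "lgamma", "geman", "scad", "laplace", "mcp", "etp", "log")

#: Default concavity parameter per family (midpoint of the standard search
#: grid; 3.7 for SCAD follows the usual recommendation).  γ is unused for l1.
DEFAULT_GAMMA = {
    "l1": 1.0,
    "lgamma": 0.2,
    "geman": 0.01,
    "scad": 3.7,
    "laplace": 0.01,
    "mcp": 0.01,
    "etp": 100.0,
    "log": 100.0,
}

#: Lower floor applied to LQA diagonal weights.  When a supergradient is
#: exactly zero (SCAD/MCP beyond γλ) and the Gram matrix is rank-deficient
#: (n < p), the ridge system could become singular; the floor keeps it
#: positive-definite without materially changing the estimates.
WEIGHT_FLOOR = 1e-12

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its (λ, γ) parameters.

    Parameters
    ----------
    family : str
        One of ``FAMILIES``.
    lam : float, default 1.0
        Sparsity weight λ ≥ 0.
    gamma : float, optional
        Concavity parameter γ.  Defaults to ``DEFAULT_GAMMA[family]``.
        Admissible range depends on the family: 0 < γ < 1 for ``lgamma``,
        γ > 2 for ``scad``, γ > 0 otherwise; ignored for ``l1``.
    """

    family: str
    lam: float = 1.0
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown penalty family {self.family!r}; expected one of {FAMILIES}"
            )
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be a finite nonnegative real, got {self.lam}")
        if self.gamma is None:
            object.__setattr__(self, "gamma", DEFAULT_GAMMA[self.family])
        g = self.gamma
        if not np.isfinite(g) or g <= 0:
            raise ValueError(f"gamma must be a finite positive real, got {g}")
        if self.family == "lgamma" and not g < 1:
            raise ValueError(f"lgamma penalty requires 0 < gamma < 1, got {g}")
        if self.family == "scad" and not g > 2:
            raise ValueError(f"scad penalty requires gamma > 2, got {g}")


def _check_magnitudes(t: ArrayLike) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("penalty argument must be a finite nonnegative magnitude")
    return arr


def _scalar_out(out: np.ndarray, t: ArrayLike) -> ArrayLike:
    return float(out) if np.ndim(t) == 0 else out


def penalty_value(t: ArrayLike, spec: PenaltySpec) -> ArrayLike:
    """Evaluate P_{λ,γ}(t) at nonnegative magnitudes ``t`` (elementwise)."""
    t = _check_magnitudes(t)
    lam, g = spec.lam, spec.gamma
    f = spec.family
    if f == "l1":
        out = lam * t
    elif f == "lgamma":
        out = lam * t ** g
    elif f == "geman":
        out = lam * t / (t + g)
    elif f == "scad":
        out = np.where(
            t <= lam,
            lam * t,
            np.where(
                t >= g * lam,
                lam ** 2 * (g + 1) / 2.0,
                (-(t ** 2) + 2 * g * lam * t - lam ** 2) / (2 * (g - 1)),
            ),
        )
    elif f == "laplace":
        out = lam * (1.0 - np.exp(-t / g))
    elif f == "mcp":
        out = np.where(t <= g * lam, lam * t - t ** 2 / (2 * g), 0.5 * g * lam ** 2)
    elif f == "etp":
        out = lam / (1.0 - np.exp(-g)) * (1.0 - np.exp(-g * t))
    else:  # log
        out = lam / np.log(g + 1.0) * np.log(g * t + 1.0)
    return _scalar_out(np.asarray(out, dtype=float), t)


def supergradient(t: ArrayLike, spec: PenaltySpec) -> ArrayLike:
    """Evaluate the supergradient P′_{λ,γ}(t) at nonnegative ``t``.

    Returns ``inf`` only for the ``lgamma`` family at t = 0, where the
    bridge penalty has an unbounded slope.
    """
    t = _check_magnitudes(t)
    lam, g = spec.lam, spec.gamma
    f = spec.family
    if f == "l1":
        out = np.full_like(t, lam)
    elif f == "lgamma":
        with np.errstate(divide="ignore"):
            out = np.where(t == 0, np.inf, lam * g * np.maximum(t, 1e-300) ** (g - 1))
    elif f == "geman":
        out = lam * g / (t + g) ** 2
    elif f == "scad":
        out = np.where(
            t <= lam, lam, np.where(t >= g * lam, 0.0, (g * lam - t) / (g - 1))
        )
    elif f == "laplace":
        out = lam / g * np.exp(-t / g)
    elif f == "mcp":
        out = np.where(t <= g * lam, lam - t / g, 0.0)
    elif f == "etp":
        out = lam * g / (1.0 - np.exp(-g)) * np.exp(-g * t)
    else:  # log
        out = lam * g / ((g * t + 1.0) * np.log(g + 1.0))
    return _scalar_out(np.asarray(out, dtype=float), t)


def penalty_sum(w: np.ndarray, spec: PenaltySpec) -> float:
    """Σ_i P_{λ,γ}(|w_i|) over a loading vector ``w``."""
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("loading vector contains non-finite entries")
    return float(np.sum(penalty_value(np.abs(w), spec)))


def lqa_diag_weights(
    w: np.ndarray, spec: PenaltySpec, zeta: float = 1e-6
) -> np.ndarray:
    """Perturbed LQA diagonal weights P′(max(|w_i|, ζ)) / (|w_i| + ζ).

    The perturbation ζ keeps the denominator positive at zero coefficients;
    the supergradient is evaluated at max(|w_i|, ζ) so that the lgamma
    family (whose slope is infinite at 0) also yields finite weights.
    Entries are floored at ``WEIGHT_FLOOR``.
    """
    if not (np.isfinite(zeta) and zeta > 0):
        raise ValueError(f"zeta must be a tiny positive real, got {zeta}")
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("loading vector contains non-finite entries")
    a = np.abs(w)
    grad = supergradient(np.maximum(a, zeta), spec)
    return np.maximum(np.asarray(grad) / (a + zeta), WEIGHT_FLOOR)
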