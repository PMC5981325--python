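"""Noisy private perception of the cooperation consequence.

Individuals never observe the true consequence ``c``; they observe a
perceived value ``c_p`` drawn from a beta distribution (rescaled to the
support [-3, 1]) whose mode equals ``c`` and whose variance scales with
an uncertainty parameter ``u``.

The distribution is parametrised as ``Beta(1 + kappa*m, 1 + kappa*(1-m))``
where ``m`` is the mode on the unit scale: this family keeps the mode at
``m`` for every concentration ``kappa >= 0``, interpolating between the
uniform distribution (kappa = 0) and a point mass (kappa -> inf).  The
unit-scale variance is set to ``u/12`` so that u = 1 reproduces the
uniform distribution exactly (variance 1/12) and u = 0 degenerates to
``c_p = c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game_core import C_HI, C_LO

#: absolute tolerance on the unit-scale variance reached by bisection
VARIANCE_TOL = 1e-10


@dataclass(frozen=True)
class PerceptionModel:
    """Uncertainty level and support of the perceived consequence."""

    u: float
    lo: float = C_LO
    hi: float = C_HI

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0):
            raise ValueError(f"u={self.u} outside [0, 1]")
        if not self.lo < self.hi:
            raise ValueError("lo must be below hi")


def _beta_variance(kappa: float, m: float) -> float:
    a = 1.0 + kappa * m
    b = 1.0 + kappa * (1.0 - m)
    s = a + b
    return a * b / (s * s * (s + 1.0))


def kappa_for_variance(m: float, target: float) -> float:
    """Concentration ``kappa`` with unit-scale variance ``target``.

    The variance of ``Beta(1+kappa*m, 1+kappa*(1-m))`` decreases
    monotonically in kappa from 1/12 at kappa = 0, so bisection on a
    doubling bracket always converges.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"mode m={m} outside [0, 1]")
    if not 0.0 < target <= 1.0 / 12.0 + 1e-15:
        raise ValueError(f"variance target {target} outside (0, 1/12]")
    if _beta_variance(0.0, m) <= target + VARIANCE_TOL:
        return 0.0
    lo, hi = 0.0, 1.0
    while _beta_variance(hi, m) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - signals a bug
            raise RuntimeError("failed to bracket kappa")
    while True:
        mid = 0.5 * (lo + hi)
        v = _beta_variance(mid, m)
        if abs(v - target) < VARIANCE_TOL or hi - lo < 1e-14:
            return mid
        if v > target:
            lo = mid
        else:
            hi = mid


def beta_shape_params(c: float, u: float,
                      lo: float = C_LO, hi: float = C_HI) -> tuple[float, float]:
    """Shape parameters (alpha, beta) of the perception distribution.

    Valid for u in (0, 1]; u = 0 is a point mass handled by the caller.
    """
    if not lo <= c <= hi:
        raise ValueError(f"c={c} outside [{lo}, {hi}]")
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u={u} outside (0, 1]")
    m = (c - lo) / (hi - lo)
    kappa = kappa_for_variance(m, u / 12.0)
    return 1.0 + kappa * m, 1.0 + kappa * (1.0 - m)


def perceive(c: float, model: PerceptionModel, rng: np.random.Generator) -> float:
    """Draw one perceived consequence ``c_p``.

    Returns exactly ``c`` when u = 0; otherwise a draw from the rescaled
    mode-``c`` beta distribution, always inside [lo, hi].
    """
    if model.u == 0.0:
        return c
    a, b = beta_shape_params(c, model.u, model.lo, model.hi)
    return model.lo + (model.hi - model.lo) * rng.beta(a, b)


def kappa_for_variance_vec(m: np.ndarray, target: float) -> np.ndarray:
    """Vectorised bisection companion of :func:`kappa_for_variance`."""
    m = np.asarray(m, dtype=float)
    if target >= 1.0 / 12.0 - VARIANCE_TOL:
        return np.zeros_like(m)
    hi = np.full_like(m, 1.0)
    for _ in range(64):
        over = _beta_variance_arr(hi, m) > target
        if not over.any():
            break
        hi[over] *= 2.0
    lo = np.zeros_like(m)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        over = _beta_variance_arr(mid, m) > target
        lo = np.where(over, mid, lo)
        hi = np.where(over, hi, mid)
    return 0.5 * (lo + hi)


def _beta_variance_arr(kappa: np.ndarray, m: np.ndarray) -> np.ndarray:
    a = 1.0 + kappa * m
    b = 1.0 + kappa * (1.0 - m)
    s = a + b
    return a * b / (s * s * (s + 1.0))


def perceive_many(c: np.ndarray, u: float, rng: np.random.Generator,
                  lo: float = C_LO, hi: float = C_HI) -> np.ndarray:
    """Vectorised :func:`perceive` for an array of true consequences."""
    c = np.asarray(c, dtype=float)
    if u == 0.0:
        return c.copy()
    m = (c - lo) / (hi - lo)
    kappa = kappa_for_variance_vec(m, u / 12.0)
    a = 1.0 + kappa * m
    b = 1.0 + kappa * (1.0 - m)
    return lo + (hi - lo) * rng.beta(a, b)
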