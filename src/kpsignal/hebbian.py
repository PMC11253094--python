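"""Hebbian pattern association and Hopfield energy landscapes.

Cross-modal stimulus-response mappings (optical, acoustic, electrical) are
modelled as a single-layer pattern-association network trained with the
Hebbian rule

    dw_ij = epsilon * alpha_i * alpha_j

for input activity alpha_i, output activity alpha_j and learning rate
epsilon.  Digitized patterns use {0, 1} bits (6-bit optical, 7-bit
acoustic/electrical vectors); a symmetric {-1, +1} coding is available for
Hopfield-style analysis.  The collective stability of an activity vector
alpha under square weights w is scored by the Hopfield energy

    E = -0.5 * sum_i sum_j w_ij * alpha_j * alpha_i

whose minima mark attractor states; the landscape utility sweeps E over a
grid of two selected unit activities with the remaining units clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ActivityPattern",
    "WeightMatrix",
    "EnergyLandscape",
    "hebbian_delta",
    "train_association",
    "binarize_response",
    "network_energy",
    "energy_landscape",
]

DEFAULT_EPSILON = 0.1
DEFAULT_GRID = 41


@dataclass
class ActivityPattern:
    """Unit activities: binary {0,1} bits for digitized patterns or reals
    for scalar stimuli.  ``modality`` is free-form ('optical', 'acoustic',
    'electrical')."""

    values: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))

    @property
    def width(self) -> int:
        return self.values.size

    @property
    def is_binary(self) -> bool:
        return bool(np.all(np.isin(self.values, (0.0, 1.0))))

    def to_symmetric(self) -> "ActivityPattern":
        """Map {0,1} bits onto the {-1,+1} coding used in Hopfield analysis."""
        if not self.is_binary:
            raise ValueError("symmetric coding requires a {0,1} binary pattern")
        return ActivityPattern(2.0 * self.values - 1.0, self.modality)


@dataclass
class WeightMatrix:
    """inputs x outputs association weights with the learning rate used."""

    w: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")


def _as_vector(alpha) -> np.ndarray:
    if isinstance(alpha, ActivityPattern):
        return alpha.values
    return np.atleast_1d(np.asarray(alpha, dtype=float))


def hebbian_delta(alpha_in, alpha_out, epsilon: float = DEFAULT_EPSILON
                  ) -> np.ndarray:
    """Weight change dw_ij = epsilon * alpha_i * alpha_j (scaled outer product)."""
    a, b = _as_vector(alpha_in), _as_vector(alpha_out)
    if not np.isfinite(epsilon):
        raise ValueError("epsilon must be finite")
    return epsilon * np.outer(a, b)


def train_association(
    pairs: Iterable[tuple[Sequence[float], Sequence[float]]],
    epsilon: float = DEFAULT_EPSILON,
    w0: np.ndarray | None = None,
) -> WeightMatrix:
    """Accumulate Hebbian updates over (input, output) pattern pairs.

    Training is a pure sum of outer products, hence order-invariant and
    additive in repeated presentations.  ``w0`` defaults to zeros shaped by
    the first pair.
    """
    pairs = [( _as_vector(a), _as_vector(b)) for a, b in pairs]
    if w0 is None:
        if not pairs:
            raise ValueError("need w0 or at least one training pair")
        w = np.zeros((pairs[0][0].size, pairs[0][1].size))
    else:
        w = np.array(w0, dtype=float)
    for a, b in pairs:
        if (a.size, b.size) != w.shape:
            raise ValueError(
                f"pair shape ({a.size}, {b.size}) does not match weights {w.shape}"
            )
        w = w + hebbian_delta(a, b, epsilon)
    return WeightMatrix(w=w, epsilon=epsilon)


def binarize_response(
    analog: float | Sequence[float],
    thresholds: Sequence[float],
    width: int | None = None,
    modality: str = "",
) -> ActivityPattern:
    """Digitize an analog response into a {0,1} activation vector.

    Bit ``b`` fires iff the analog value exceeds ``thresholds[b]``: a scalar
    stimulus is compared against every threshold (a thermometer code); a
    vector response compares channel ``b`` against its own threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if width is None:
        width = thresholds.size
    if width < 1 or thresholds.size != width:
        raise ValueError("thresholds length must equal width >= 1")
    analog = np.asarray(analog, dtype=float)
    if analog.ndim == 0:
        bits = (analog > thresholds).astype(float)
    else:
        if analog.size != width:
            raise ValueError(
                f"vector response has {analog.size} values for width {width}"
            )
        bits = (analog > thresholds).astype(float)
    return ActivityPattern(bits, modality)


def network_energy(w: np.ndarray | WeightMatrix, alpha) -> float:
    """Hopfield energy E = -0.5 * alpha^T w alpha for square weights w.

    For symmetric w with zero diagonal this is the standard Hopfield
    energy; for asymmetric w the bilinear form sees only the symmetric part
    (w + w^T)/2.
    """
    w = w.w if isinstance(w, WeightMatrix) else np.atleast_2d(np.asarray(w, dtype=float))
    a = _as_vector(alpha)
    if w.shape[0] != w.shape[1] or w.shape[0] != a.size:
        raise ValueError(
            f"weights must be square with dimension len(alpha)={a.size}, got {w.shape}"
        )
    return float(-0.5 * a @ w @ a)


@dataclass
class EnergyLandscape:
    """Energy surface over two unit activities, others clamped."""

    axis1: np.ndarray
    axis2: np.ndarray
    energy: np.ndarray          # shape (len(axis1), len(axis2))
    unit_a: int
    unit_b: int
    fixed: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_long_frame(self):
        """Long-format table with columns activity1, activity2, energy."""
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame({"activity1": a1.ravel(), "activity2": a2.ravel(),
                             "energy": self.energy.ravel()})


def energy_landscape(
    w: np.ndarray | WeightMatrix,
    unit_a: int,
    unit_b: int,
    range_a: tuple[float, float] = (-1.0, 1.0),
    range_b: tuple[float, float] = (-1.0, 1.0),
    grid: int = DEFAULT_GRID,
    fixed: Sequence[float] | None = None,
) -> EnergyLandscape:
    """Sweep the Hopfield energy over a grid of two unit activities.

    The remaining units are clamped at ``fixed`` (default 0), so the
    surface is an exact quadratic in (alpha_a, alpha_b).
    """
    wm = w.w if isinstance(w, WeightMatrix) else np.atleast_2d(np.asarray(w, dtype=float))
    n = wm.shape[0]
    if unit_a == unit_b:
        raise ValueError("unit_a and unit_b must be distinct")
    if not (0 <= unit_a < n and 0 <= unit_b < n):
        raise ValueError(f"unit indices must lie in [0, {n})")
    base = np.zeros(n) if fixed is None else np.asarray(fixed, dtype=float).copy()
    if base.size != n:
        raise ValueError(f"fixed activities must have length {n}")

    axis1 = np.linspace(*range_a, grid)
    axis2 = np.linspace(*range_b, grid)
    energy = np.empty((grid, grid))
    alpha = base.copy()
    for i, va in enumerate(axis1):
        alpha[unit_a] = va
        for j, vb in enumerate(axis2):
            alpha[unit_b] = vb
            energy[i, j] = network_energy(wm, alpha)
    return EnergyLandscape(axis1=axis1, axis2=axis2, energy=energy,
                           unit_a=unit_a, unit_b=unit_b, fixed=base)
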