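"""Stage survival rates and the cubic survival-versus-temperature curve.

Generation survival of this species is dome-shaped in temperature over the
21-30 °C range where the full life cycle completes; a cubic polynomial
Y = aT³ + bT² + cT + d is fit to percent survival and its interior maximum —
where dY/dT = 0 with d²Y/dT² < 0 — is the optimum rearing temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    InconsistentCountError,
    NoOptimumError,
    UnderdeterminedFitError,
    UndefinedRateError,
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def survival_rate(n_advancing: int, n_entering: int, ndigits: int | None = 2) -> float:
    """Percent of individuals progressing to the next stage, 100·N1/N2.

    ``ndigits`` controls presentation rounding (half-up, default two
    decimals as printed in life tables); pass ``None`` for full precision.
    """
    if n_entering == 0:
        raise UndefinedRateError("survival undefined: no individuals entered")
    if n_advancing < 0 or n_entering < 0:
        raise InconsistentCountError("counts must be nonnegative")
    if n_advancing > n_entering:
        raise InconsistentCountError(
            f"{n_advancing} advanced but only {n_entering} entered"
        )
    pct = 100.0 * n_advancing / n_entering
    return pct if ndigits is None else round_half_up(pct, ndigits)


@dataclass(frozen=True)
class SurvivalCurve:
    """Fitted cubic percent-survival curve on a temperature interval.

    ``coefficients`` are (a, b, c, d) in descending degree; ``fit_range``
    is the (low, high) °C interval the fit is valid on.
    """

    coefficients: tuple[float, float, float, float]
    fit_range: tuple[float, float]

    def __call__(self, temperature: float | np.ndarray) -> float | np.ndarray:
        return np.polyval(self.coefficients, temperature)

    def derivative_roots(self) -> np.ndarray:
        """Real roots of dY/dT = 3aT² + 2bT + c, ascending."""
        a, b, c, _ = self.coefficients
        roots = np.roots([3.0 * a, 2.0 * b, c])
        real = roots[np.abs(roots.imag) < 1e-9].real
        return np.sort(real)


def fit_survival_cubic(
    observations: Iterable[tuple[float, float]],
    fit_range: tuple[float, float] = (21.0, 30.0),
) -> SurvivalCurve:
    """Least-squares cubic of percent survival on temperature.

    Parameters
    ----------
    observations
        (temperature °C, survival percent) pairs; at least four within
        ``fit_range`` are required.  With exactly four the result is the
        unique interpolating cubic.
    """
    lo, hi = fit_range
    pts = [(t, y) for t, y in observations if lo <= t <= hi]
    if len(pts) < 4:
        raise UnderdeterminedFitError(
            f"cubic fit needs >= 4 observations in [{lo}, {hi}] °C, "
            f"got {len(pts)}"
        )
    T = np.array([p[0] for p in pts], dtype=float)
    Y = np.array([p[1] for p in pts], dtype=float)
    coeffs = np.polyfit(T, Y, deg=3)
    return SurvivalCurve(coefficients=tuple(float(c) for c in coeffs),
                         fit_range=(float(lo), float(hi)))


def optimal_temperature(curve: SurvivalCurve, ndigits: int | None = 2) -> float:
    """Interior maximum of the cubic on its fit range, in °C.

    Solved in closed form: the stationary points are the roots of the
    derivative quadratic; the maximum is the root with negative second
    derivative lying strictly inside ``fit_range``.

    Raises
    ------
    NoOptimumError
        If no stationary point inside the range is a maximum — including
        curves whose derivative has no real root at all.
    """
    a, b, _, _ = curve.coefficients
    lo, hi = curve.fit_range
    candidates = [
        t for t in curve.derivative_roots()
        if lo < t < hi and (6.0 * a * t + 2.0 * b) < 0
    ]
    if not candidates:
        raise NoOptimumError(
            f"no interior maximum on [{lo}, {hi}] °C for coefficients "
            f"{curve.coefficients}"
        )
    # a cubic has at most one interior maximum
    t_opt = float(candidates[0])
    return t_opt if ndigits is None else round_half_up(t_opt, ndigits)


def generation_survival(stage_fractions: Sequence[float]) -> float:
    """Whole-generation survival as the product of stage fractions."""
    out = 1.0
    for f in stage_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"survival fraction {f} outside [0, 1]")
        out *= f
    return out
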