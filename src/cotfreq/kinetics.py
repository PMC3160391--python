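"""Second-order DNA reassociation (Cot) kinetics.

Sheared, denatured genomic DNA reassociates by second-order kinetics: for a
sequence class present at concentration proportional to its copy number the
single-stranded fraction after renaturation to a given Cot value
(Cot = C0 * t, initial single-strand nucleotide concentration times time,
mol*s/L) follows the classic hyperbola

    S(Cot) = 1 / (1 + k * Cot),        k = k_base * copy_number.

High-copy families reanneal at low Cot; Cot filtration retains the
still-single-stranded material, so a Cot-selected read set is depleted of
repeats in a copy-number-dependent way.  Projecting an element's read
fraction in two or more Cot fractions back to Cot = 0 ("time zero", where no
depletion has occurred) estimates its genome-wide fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class KineticsError(ValueError):
    pass


class ExtrapolationWarning(UserWarning):
    """Emitted when a fitted Cot-zero fraction leaves [0, 1] and is clamped."""


EXTRAPOLATION_MODES = ("linear", "loglinear")


@dataclass(frozen=True)
class KineticsParams:
    """Renaturation parameters.

    c0: initial single-strand nucleotide concentration (mol nt / L).
    k_base: reassociation rate constant per unit copy number (L/(mol*s)).
    """

    c0: float
    k_base: float

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise KineticsError(f"c0 must be positive, got {self.c0}")
        if self.k_base <= 0:
            raise KineticsError(f"k_base must be positive, got {self.k_base}")


@dataclass(frozen=True)
class FractionPoint:
    """An element read fraction observed in one Cot-selected sample."""

    cot: float
    fraction: float

    def __post_init__(self) -> None:
        if self.cot < 0:
            raise KineticsError(f"negative Cot value {self.cot}")
        if not 0.0 <= self.fraction <= 1.0:
            raise KineticsError(f"fraction {self.fraction} outside [0, 1]")


def cot_value(c0: float, t: float) -> float:
    """Cot value (mol*s/L) reached after renaturing for ``t`` seconds."""
    if c0 <= 0:
        raise KineticsError(f"c0 must be positive, got {c0}")
    if t < 0:
        raise KineticsError(f"negative renaturation time {t}")
    return c0 * t


def time_for_cot(cot_target: float, c0: float) -> float:
    """Seconds of renaturation needed to reach ``cot_target``; inverse of cot_value."""
    if c0 <= 0:
        raise KineticsError(f"c0 must be positive, got {c0}")
    if cot_target < 0:
        raise KineticsError(f"negative Cot target {cot_target}")
    return cot_target / c0


def format_hms(seconds: float) -> str:
    """Human-readable h:m:s for logs and reports (seconds internally)."""
    s = int(round(seconds))
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    return f"{h} hr, {m} min, {sec} sec" if h else f"{m} min {sec} sec"


def ss_survival(copy_number: float, cot: float, k_base: float) -> float:
    """Fraction of a family still single-stranded at the given Cot.

    Second-order hyperbola with the family rate proportional to its copy
    number: 1 at Cot 0, strictly decreasing in both Cot and copy number.
    """
    if copy_number < 1:
        raise KineticsError(f"copy_number must be >= 1, got {copy_number}")
    if cot < 0:
        raise KineticsError(f"negative Cot value {cot}")
    if k_base <= 0:
        raise KineticsError(f"k_base must be positive, got {k_base}")
    return 1.0 / (1.0 + k_base * copy_number * cot)


def _as_points(points: Iterable) -> list[FractionPoint]:
    out = []
    for p in points:
        if isinstance(p, FractionPoint):
            out.append(p)
        else:
            cot, frac = p
            out.append(FractionPoint(float(cot), float(frac)))
    return out


def _least_squares_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) by centred least squares.

    Centring keeps the intercept accurate for exactly-affine input (no
    Vandermonde conditioning loss); two points give exact interpolation.
    """
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    slope = float(np.dot(dx, y - ym) / np.dot(dx, dx))
    return slope, float(ym - slope * xm)


def extrapolate_to_cot_zero(points: Sequence, mode: str = "linear") -> float:
    """Estimate the Cot-zero element fraction from >= 2 fraction points.

    ``linear`` (default) fits fraction = a + b*Cot by least squares (exact
    interpolation for two points) and returns a = f(0).  ``loglinear`` fits
    fraction against log10(Cot) — such a fit diverges at Cot = 0, so it is
    evaluated one decade below the smallest measured Cot; all Cot values
    must then be positive.  Either way the result is clamped to [0, 1] with
    an :class:`ExtrapolationWarning` when the fit leaves the unit interval.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise KineticsError("extrapolation needs at least 2 Cot fraction points")
    cots = np.array([p.cot for p in pts], dtype=float)
    fracs = np.array([p.fraction for p in pts], dtype=float)
    if len(set(cots.tolist())) != len(pts):
        raise KineticsError("duplicate Cot values in extrapolation input")
    if mode == "linear":
        _slope, intercept = _least_squares_line(cots, fracs)
        f0 = float(intercept)
    elif mode == "loglinear":
        if np.any(cots <= 0):
            raise KineticsError("loglinear mode requires strictly positive Cot values")
        x = np.log10(cots)
        slope, intercept = _least_squares_line(x, fracs)
        f0 = float(intercept + slope * (np.log10(cots.min()) - 1.0))
    else:
        raise KineticsError(f"unknown extrapolation mode {mode!r}")
    if f0 < 0.0 or f0 > 1.0:
        warnings.warn(
            f"extrapolated Cot-zero fraction {f0:.6g} outside [0, 1]; clamped",
            ExtrapolationWarning,
            stacklevel=2,
        )
        f0 = min(1.0, max(0.0, f0))
    return f0
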